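"""End-to-end driver: detect -> blocks -> origin -> context -> orthology -> ancestry.

Operates on a dataset directory in the layout the simulator emits (one
subdirectory per species with ``hsps.tsv``, ``scaffolds.tsv``,
``genes.gff3``, ``repeats.bed``; a ``tree.nwk`` at the top level) and
writes per-stage result tables plus a manifest recording the seed,
thresholds and per-stage record counts.  Species lacking symbol-level gene
annotation still run through detection, origin and context but are excluded
from orthology and ancestry.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

from . import ancestry, detect, formats, origin, orthology

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    dataset_dir: str
    out_dir: str
    seed: int = 0
    mt_length: int = 16_600
    max_e: float = 1e-3
    min_len: int = 30
    nuclear_gap_max: int = 10
    mt_gap_max: int = 10
    min_contig: int = 20_000
    block_gap: int = 2_000
    span: int = 16_000
    window: int = 50
    alpha: float = 0.01
    n_reshuffle: int = 200
    min_overlap: float = 0.5
    anchor_k: int = 3
    anchor_mode: str = orthology.ANCHOR_EITHER
    max_expectation: float = 1.0
    orthology_on_blocks: bool = True
    clades: dict = field(default_factory=dict)


def run_pipeline(config: RunConfig) -> dict:
    """Run all stages; returns the manifest dictionary."""
    dataset = Path(config.dataset_dir)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "thresholds": {
            k: v for k, v in config.__dict__.items() if k not in ("clades",)
        },
        "stages": {},
    }
    species_dirs = sorted(
        p for p in dataset.iterdir() if p.is_dir() and (p / "hsps.tsv").exists()
    )
    tree = formats.read_tree(dataset / "tree.nwk")

    numts_by_species: dict[str, list] = {}
    blocks_by_species: dict[str, list] = {}
    genes_by_species: dict[str, list] = {}
    for spdir in species_dirs:
        sp = spdir.name
        index = formats.read_genome_index(spdir / "scaffolds.tsv")
        hsps = formats.read_hsp_table(spdir / "hsps.tsv")
        hsps = detect.filter_hsps(hsps, max_e=config.max_e, min_len=config.min_len)
        numts = detect.merge_hsps(
            hsps,
            config.mt_length,
            nuclear_gap_max=config.nuclear_gap_max,
            mt_gap_max=config.mt_gap_max,
            species=sp,
            genome_index=index,
        )
        numts = detect.filter_by_contig_length(
            numts, index, min_contig=config.min_contig, species=sp
        )
        blocks = detect.assemble_blocks(numts, max_gap=config.block_gap, species=sp)
        numts_by_species[sp] = numts
        blocks_by_species[sp] = blocks
        formats.write_numt_bed(out / f"{sp}.numts.bed", numts)
        gene_path = spdir / "genes.gff3"
        if gene_path.exists():
            genes = formats.read_gene_annotation(gene_path)
            if genes:
                genes_by_species[sp] = genes
            else:
                log.warning("%s: no symbol-level genes; excluded from orthology", sp)
        else:
            log.warning("%s: missing gene annotation; excluded from orthology", sp)
    manifest["stages"]["detect"] = {
        sp: {"numts": len(numts_by_species[sp]), "blocks": len(blocks_by_species[sp])}
        for sp in numts_by_species
    }

    profiles = {
        sp: origin.coverage_profile(numts, span=config.span)
        for sp, numts in numts_by_species.items()
    }
    medians = origin.window_medians(profiles, window=config.window)
    tests = origin.pairwise_window_tests(medians, alpha=config.alpha)
    null = origin.reshuffle_null(
        numts_by_species,
        n_iter=config.n_reshuffle,
        span=config.span,
        window=config.window,
        alpha=config.alpha,
        seed=config.seed,
    )
    medians.to_csv(out / "window_medians.tsv", sep="\t")
    with open(out / "origin_null.tsv", "w") as fh:
        fh.write("iteration\tn_significant\n")
        for i, c in enumerate(null.null_counts):
            fh.write(f"{i}\t{c}\n")
    manifest["stages"]["origin"] = {
        "n_tests": tests.n_tests,
        "n_significant": tests.n_significant,
        "null_median": null.null_median,
        "null_p95": null.percentile(95),
    }

    ortho_species = sorted(set(genes_by_species) & set(numts_by_species))
    rate = orthology.error_rate(
        orthology.ErrorModel(anchor_mode=orthology.ANCHOR_BOTH)
    )
    pairs: dict[tuple[str, str], list] = {}
    expectations: dict[tuple[str, str], float] = {}
    units_by_species = {}
    contexts_by_species = {}
    for sp in ortho_species:
        units = (
            blocks_by_species[sp] if config.orthology_on_blocks else numts_by_species[sp]
        )
        units_by_species[sp] = units
        contexts_by_species[sp] = orthology.build_synteny_context(
            units, genes_by_species[sp], k=config.anchor_k
        )
    for a, b in combinations(ortho_species, 2):
        pairs[(a, b)] = orthology.assign_orthologs(
            units_by_species[a],
            contexts_by_species[a],
            units_by_species[b],
            contexts_by_species[b],
            config.mt_length,
            min_overlap=config.min_overlap,
            anchor_mode=config.anchor_mode,
            species_a=a,
            species_b=b,
        )
        expectations[(a, b)] = orthology.error_expectation(
            rate, len(units_by_species[a]), len(units_by_species[b])
        )
    with open(out / "ortholog_pairs.tsv", "w") as fh:
        fh.write("species_a\tunit_a\tspecies_b\tunit_b\toverlap\tshared_anchors\tE\n")
        for (a, b), plist in sorted(pairs.items()):
            for p in plist:
                fh.write(
                    f"{a}\t{p.unit_a}\t{b}\t{p.unit_b}\t{p.overlap:.3f}\t"
                    f"{','.join(sorted(p.shared_anchors))}\t{expectations[(a, b)]:.3g}\n"
                )
    manifest["stages"]["orthology"] = {
        "n_species": len(ortho_species),
        "n_comparisons": len(pairs),
        "n_pairs": sum(len(v) for v in pairs.values()),
    }

    all_units = {
        sp: [u.id for u in units_by_species[sp]] for sp in ortho_species
    }
    groups = ancestry.build_ortholog_groups(
        pairs,
        all_units=all_units,
        expectations=expectations,
        max_expectation=config.max_expectation,
    )
    pruned = tree  # analysis tree restricted to orthology species
    if set(pruned.tips()) - set(ortho_species):
        import dendropy

        t2 = pruned.tree.clone(depth=1)
        t2.retain_taxa_with_labels(ortho_species)
        from .core import Phylogeny

        pruned = Phylogeny.from_dendropy(t2)
    counts, support = ancestry.ancestral_counts(groups, pruned)
    rates = ancestry.insertion_rates(
        {sp: [n.id for n in numts_by_species[sp]] for sp in ortho_species},
        groups
        if not config.orthology_on_blocks
        else _numt_level_groups(groups, blocks_by_species),
        pruned,
    )
    with open(out / "ancestral_counts.tsv", "w") as fh:
        fh.write("node\tcount\tgroups\n")
        for node, c in sorted(counts.items()):
            fh.write(f"{node}\t{c}\t{','.join(support[node])}\n")
    with open(out / "insertion_rates.tsv", "w") as fh:
        fh.write("species\trate_per_myr\n")
        for sp, r in sorted(rates.items()):
            fh.write(f"{sp}\t{r:.4f}\n")
    manifest["stages"]["ancestry"] = {
        "n_groups": len(groups),
        "ancestral_counts": counts,
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True, default=str)
    return manifest


def _numt_level_groups(groups, blocks_by_species):
    """Translate block-level groups to member-NUMT ids for rate estimation."""
    from .core import OrthologGroup

    block_members = {
        sp: {b.id: [m.id for m in b.members] for b in blocks}
        for sp, blocks in blocks_by_species.items()
    }
    out = []
    for g in groups:
        members = {}
        for sp, unit_ids in g.members.items():
            numt_ids = []
            for uid in unit_ids:
                numt_ids.extend(block_members.get(sp, {}).get(uid, [uid]))
            members[sp] = tuple(sorted(numt_ids))
        out.append(OrthologGroup(id=g.id, members=members))
    return out
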