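"""Forward simulator of NUMT gain, loss and decay along a species tree.

Generates fully synthetic, truth-annotated multi-species datasets in the
exact formats the pipeline consumes: per-species genomes (optional
sequence), protein-coding gene annotations with conserved order, TE
intervals, and alignment-hit (HSP) tables emitted directly from the truth.

The model: NUMT gains arrive as a Poisson process on tree branches (rate
per Myr); each gain draws an mtDNA start from an origin-bias profile and a
length from a log-normal distribution, lands in a random inter-gene slot
of the ancestral gene order, and is inherited by descendants subject to an
exponential per-Myr loss probability.  Surviving copies accumulate
substitutions at a per-site rate over their residence time, which lowers
the emitted HSP identity accordingly.  Footprints crossing the
linearization boundary of the circular mitogenome are emitted as two HSP
rows, as a real aligner would produce.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

from . import formats
from .core import MINUS, PLUS, GeneModel, GenomeIndex, Hsp, Phylogeny, RepeatInterval

DEFAULT_TREE = "(((Aaaa:25,Bbbb:25):25,(Cccc:25,Dddd:25):25):50,(Eeee:60,Ffff:60):40);"

# Toy linearized mitogenome: tRNA-Phe + rRNA region first, 13 protein-coding
# genes with realistic proportional lengths, D-loop last.  Lengths are
# multiples of 3 so the ORF machinery sees clean reading frames.
DEFAULT_MT_GENES: tuple[tuple[str, int, int, str], ...] = (
    ("ND1", 3306, 3306 + 957, PLUS),
    ("ND2", 4469, 4469 + 1044, PLUS),
    ("COX1", 5903, 5903 + 1542, PLUS),
    ("COX2", 7585, 7585 + 684, PLUS),
    ("ATP8", 8365, 8365 + 207, PLUS),
    ("ATP6", 8600, 8600 + 681, PLUS),
    ("COX3", 9300, 9300 + 783, PLUS),
    ("ND3", 10090, 10090 + 345, PLUS),
    ("ND4L", 10469, 10469 + 297, PLUS),
    ("ND4", 10800, 10800 + 1377, PLUS),
    ("ND5", 12336, 12336 + 1812, PLUS),
    ("ND6", 14160, 14160 + 525, MINUS),
    ("CYTB", 14746, 14746 + 1140, PLUS),
)


@dataclass
class SimConfig:
    """Study conditions for one synthetic dataset; the seed is mandatory."""

    seed: int
    tree_newick: str = DEFAULT_TREE
    mt_length: int = 16_600
    n_scaffolds: int = 2
    scaffold_length: int = 1_000_000
    n_genes: int = 200
    gene_length: int = 2_000
    te_density: float = 0.35
    te_mean_length: float = 500.0
    gain_rate_per_myr: float = 0.7
    numt_length_log_mu: float = math.log(150.0)
    numt_length_log_sigma: float = 1.0
    numt_min_length: int = 30
    numt_max_length: int = 16_000
    loss_rate_per_myr: float = 0.02
    sub_rate_per_myr: float = 0.002
    origin_bias: tuple[tuple[int, int, float], ...] | None = None
    rearrangement_rate_per_myr: float = 0.0
    emit_sequences: bool = True

    def validate(self) -> None:
        for name in (
            "te_density",
            "gain_rate_per_myr",
            "loss_rate_per_myr",
            "sub_rate_per_myr",
            "rearrangement_rate_per_myr",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.numt_min_length < 1:
            raise ValueError("numt_min_length must be >= 1")


@dataclass
class NumtEvent:
    id: str
    gain_node: str  # label of the node below the gain branch
    gain_age: float  # Myr before present
    mt_intervals: tuple[tuple[int, int], ...]
    orientation: str
    scaffold: int  # ancestral scaffold index
    left_gene: str  # gene immediately upstream of the insertion slot
    offset_fraction: float
    length: int


@dataclass
class CopyRecord:
    species: str
    scaffold: str
    n_start: int
    n_end: int
    orientation: str
    identity: float
    n_subs: int


@dataclass
class TruthTable:
    events: list[NumtEvent]
    copies: dict[str, dict[str, CopyRecord]]  # event id -> species -> copy

    def presence(self, event_id: str) -> frozenset[str]:
        return frozenset(self.copies.get(event_id, {}))

    def surviving_events(self) -> list[NumtEvent]:
        return [e for e in self.events if self.copies.get(e.id)]

    def true_ancestral_counts(self, tree: Phylogeny) -> dict[str, int]:
        """Events ancestral per node under the both-child-clades rule."""
        counts: dict[str, int] = {}
        for node in tree.internal_nodes():
            left, right = node.child_nodes()
            lt, rt = Phylogeny.tip_set(left), Phylogeny.tip_set(right)
            counts[tree.node_label(node)] = sum(
                1
                for e in self.events
                if self.presence(e.id) & lt and self.presence(e.id) & rt
            )
        return counts


@dataclass
class SpeciesData:
    species: str
    genome_index: GenomeIndex
    genes: list[GeneModel]
    repeats: list[RepeatInterval]
    hsps: list[Hsp]
    genome_seqs: dict[str, str] | None = None


@dataclass
class SimResult:
    config: SimConfig
    tree: Phylogeny
    species: list[str]
    data: dict[str, SpeciesData]
    truth: TruthTable
    mt_genes: list[GeneModel]
    mitogenome: str | None = None


_BASES = np.array(list("ACGT"))
_MT_STOPS = {"TAA", "TAG", "AGA", "AGG"}  # vertebrate-mitochondrial stops


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length)


def _codons_no_mt_stop(rng: np.random.Generator, n: int) -> list[str]:
    out = []
    while len(out) < n:
        codon = "".join(_BASES[rng.integers(0, 4, size=3)])
        if codon not in _MT_STOPS:
            out.append(codon)
    return out


def _revcomp_codes(arr: np.ndarray) -> np.ndarray:
    return (3 - arr)[::-1]  # A<->T, C<->G in 0..3 encoding


def _seq_str(arr: np.ndarray) -> str:
    return "".join(_BASES[arr])


class _Layout:
    """Deterministic gene layout: evenly spaced slots per scaffold."""

    def __init__(self, cfg: SimConfig):
        self.genes_per_scaffold = cfg.n_genes // cfg.n_scaffolds
        if self.genes_per_scaffold < 2:
            raise ValueError("need >=2 genes per scaffold")
        self.spacing = cfg.scaffold_length // self.genes_per_scaffold
        self.margin = 100
        self.gap_capacity = self.spacing - cfg.gene_length - 2 * self.margin
        if self.gap_capacity < cfg.numt_min_length:
            raise ValueError(
                "infeasible placement: inter-gene gaps "
                f"({self.gap_capacity} bp) cannot hold a {cfg.numt_min_length} bp NUMT; "
                "increase scaffold_length or reduce n_genes"
            )
        self.gene_length = cfg.gene_length
        self.scaffold_length = cfg.scaffold_length

    def gene_start(self, slot: int) -> int:
        return slot * self.spacing + self.spacing // 4

    def gap_region(self, slot: int) -> tuple[int, int]:
        """Usable insertion region of the gap following the gene at ``slot``."""
        gap_start = self.gene_start(slot) + self.gene_length + self.margin
        gap_end = self.gene_start(slot + 1) - self.margin
        return gap_start, min(gap_end, self.scaffold_length - self.margin)


def _simulate_gene_orders(
    tree: Phylogeny, cfg: SimConfig, layout: _Layout, rng: np.random.Generator
) -> dict[str, list[list[str]]]:
    """Per-species gene order per scaffold, with lineage rearrangements."""
    n_digits = max(4, len(str(cfg.n_genes)))
    ancestral = [
        [
            f"g{scaf * layout.genes_per_scaffold + j + 1:0{n_digits}d}"
            for j in range(layout.genes_per_scaffold)
        ]
        for scaf in range(cfg.n_scaffolds)
    ]
    orders: dict[str, list[list[str]]] = {}

    def descend(node, order: list[list[str]]) -> None:
        order = [list(s) for s in order]
        if node.parent_node is not None and cfg.rearrangement_rate_per_myr > 0:
            n_events = rng.poisson(cfg.rearrangement_rate_per_myr * node.edge.length)
            for _ in range(n_events):
                scaf = int(rng.integers(0, cfg.n_scaffolds))
                row = order[scaf]
                seg_len = int(rng.integers(1, min(10, len(row) // 2) + 1))
                i = int(rng.integers(0, len(row) - seg_len + 1))
                seg = row[i : i + seg_len]
                rest = row[:i] + row[i + seg_len :]
                j = int(rng.integers(0, len(rest) + 1))
                order[scaf] = rest[:j] + seg + rest[j:]
        if not node.child_nodes():
            orders[node.taxon.label] = order
        for child in node.child_nodes():
            descend(child, order)

    descend(tree.root, ancestral)
    return orders


def _origin_probabilities(cfg: SimConfig) -> np.ndarray | None:
    if not cfg.origin_bias:
        return None
    weights = np.ones(cfg.mt_length)
    for s, e, w in cfg.origin_bias:
        weights[s:e] += w
    return weights / weights.sum()


def _draw_events(
    tree: Phylogeny, cfg: SimConfig, layout: _Layout, rng: np.random.Generator
) -> list[NumtEvent]:
    probs = _origin_probabilities(cfg)
    events: list[NumtEvent] = []
    counter = 0
    max_len = min(cfg.numt_max_length, layout.gap_capacity, cfg.mt_length)
    for node in tree.tree.preorder_node_iter():
        # the root's own edge (a stem above the root) can also carry gains
        edge_len = node.edge.length or 0.0
        if not edge_len:
            continue
        n_gains = rng.poisson(cfg.gain_rate_per_myr * edge_len)
        for _ in range(n_gains):
            counter += 1
            length = int(
                round(rng.lognormal(cfg.numt_length_log_mu, cfg.numt_length_log_sigma))
            )
            length = int(np.clip(length, cfg.numt_min_length, max_len))
            if probs is None:
                mt_start = int(rng.integers(0, cfg.mt_length))
            else:
                mt_start = int(rng.choice(cfg.mt_length, p=probs))
            if mt_start + length <= cfg.mt_length:
                intervals = ((mt_start, mt_start + length),)
            else:
                intervals = (
                    (mt_start, cfg.mt_length),
                    (0, mt_start + length - cfg.mt_length),
                )
            scaf = int(rng.integers(0, cfg.n_scaffolds))
            slot = int(rng.integers(0, layout.genes_per_scaffold - 1))
            gain_age = tree.age(node) + float(rng.uniform(0, edge_len))
            events.append(
                NumtEvent(
                    id=f"ev_{counter}",
                    gain_node=tree.node_label(node),
                    gain_age=gain_age,
                    mt_intervals=intervals,
                    orientation=PLUS if rng.random() < 0.5 else MINUS,
                    scaffold=scaf,
                    left_gene=f"g{scaf * layout.genes_per_scaffold + slot + 1:0{max(4, len(str(cfg.n_genes)))}d}",
                    offset_fraction=float(rng.random()),
                    length=length,
                )
            )
    return events


def _inherit(
    tree: Phylogeny,
    events: list[NumtEvent],
    cfg: SimConfig,
    rng: np.random.Generator,
) -> dict[str, set[str]]:
    """Which tips carry each event, after per-branch exponential loss."""
    label_to_node = {tree.node_label(n): n for n in tree.tree.preorder_node_iter()}
    carriers: dict[str, set[str]] = {}
    for ev in events:
        node = label_to_node[ev.gain_node]
        tips: set[str] = set()

        def walk(n, alive: bool) -> None:
            if not alive:
                return
            if not n.child_nodes():
                tips.add(n.taxon.label)
                return
            for child in n.child_nodes():
                p_keep = math.exp(-cfg.loss_rate_per_myr * child.edge.length)
                walk(child, rng.random() < p_keep)

        # survival from the gain point to the bottom of the gain branch
        p_keep0 = math.exp(
            -cfg.loss_rate_per_myr * max(0.0, ev.gain_age - tree.age(node))
        )
        if rng.random() < p_keep0:
            if not node.child_nodes():
                tips.add(node.taxon.label)
            else:
                for child in node.child_nodes():
                    p_keep = math.exp(-cfg.loss_rate_per_myr * child.edge.length)
                    walk(child, rng.random() < p_keep)
        carriers[ev.id] = tips
    return carriers


def _place_copies(
    tree: Phylogeny,
    events: list[NumtEvent],
    carriers: Mapping[str, set[str]],
    orders: Mapping[str, list[list[str]]],
    cfg: SimConfig,
    layout: _Layout,
    rng: np.random.Generator,
) -> TruthTable:
    copies: dict[str, dict[str, CopyRecord]] = {e.id: {} for e in events}
    by_event = {e.id: e for e in events}
    for sp in tree.tips():
        order = orders[sp]
        # index of each gene in this species' order
        pos = {
            sym: (scaf, j)
            for scaf, row in enumerate(order)
            for j, sym in enumerate(row)
        }
        # group events carried by this species by their insertion gap
        per_gap: dict[tuple[int, int], list[NumtEvent]] = {}
        for ev in events:
            if sp not in carriers[ev.id]:
                continue
            scaf, j = pos[ev.left_gene]
            if j >= layout.genes_per_scaffold - 1:
                j = layout.genes_per_scaffold - 2  # slot slid to scaffold end
            per_gap.setdefault((scaf, j), []).append(ev)
        for (scaf, j), evs in per_gap.items():
            gap_start, gap_end = layout.gap_region(j)
            evs = sorted(evs, key=lambda e: (e.offset_fraction, e.id))
            total = sum(e.length for e in evs) + 200 * (len(evs) - 1)
            if total > gap_end - gap_start:
                raise ValueError(
                    "infeasible placement: "
                    f"{len(evs)} NUMTs totalling {total} bp exceed the "
                    f"{gap_end - gap_start} bp inter-gene gap on scaffold {scaf}"
                )
            cursor = gap_start
            span = gap_end - gap_start
            for ev in evs:
                slack = gap_end - cursor - (
                    sum(e.length for e in evs[evs.index(ev) :])
                    + 200 * (len(evs) - evs.index(ev) - 1)
                )
                offset = int(ev.offset_fraction * max(slack, 0))
                start = cursor + offset
                end = start + ev.length
                cursor = end + 200
                p_sub = 1.0 - math.exp(-cfg.sub_rate_per_myr * ev.gain_age)
                n_subs = int(rng.binomial(ev.length, p_sub))
                copies[ev.id][sp] = CopyRecord(
                    species=sp,
                    scaffold=f"{sp}_scaf{scaf + 1}",
                    n_start=start,
                    n_end=end,
                    orientation=ev.orientation,
                    identity=100.0 * (1.0 - n_subs / ev.length),
                    n_subs=n_subs,
                )
    return TruthTable(events=events, copies=copies)


def _copy_to_hsps(
    ev: NumtEvent, copy: CopyRecord, mt_length: int
) -> list[Hsp]:
    """Emit one HSP per footprint interval, splitting at the wrap boundary."""
    parts = ev.mt_intervals
    lengths = [e - s for s, e in parts]
    total = sum(lengths)
    # distribute substitutions proportionally across split parts
    subs = [int(round(copy.n_subs * l / total)) for l in lengths]
    subs[-1] = copy.n_subs - sum(subs[:-1])
    rows: list[Hsp] = []
    # nuclear order of parts: plus keeps footprint order; minus reverses it
    order = range(len(parts)) if copy.orientation == PLUS else range(len(parts) - 1, -1, -1)
    n_cursor = copy.n_start
    for idx in order:
        s, e = parts[idx]
        part_len = e - s
        n_s, n_e = n_cursor, n_cursor + part_len
        n_cursor = n_e
        identity = 100.0 * (1.0 - subs[idx] / part_len)
        rows.append(
            Hsp(
                mt_start=s,
                mt_end=e,
                scaffold=copy.scaffold,
                n_start=n_s,
                n_end=n_e,
                orientation=copy.orientation,
                identity=round(identity, 3),
                aln_length=part_len,
                e_value=10.0 ** (-min(180.0, part_len / 2.0)),
                bit_score=round(1.9 * part_len, 1),
                mismatches=subs[idx],
                gap_opens=0,
            )
        )
    return rows


def _simulate_repeats(
    cfg: SimConfig, scaffold: str, rng: np.random.Generator
) -> list[RepeatInterval]:
    target = cfg.te_density * cfg.scaffold_length
    placed = 0.0
    out: list[RepeatInterval] = []
    classes = ("LINE/L1", "SINE/Alu", "LTR/ERVL", "DNA/hAT")
    while placed < target:
        length = max(50, int(rng.exponential(cfg.te_mean_length)))
        start = int(rng.integers(0, max(1, cfg.scaffold_length - length)))
        out.append(
            RepeatInterval(
                scaffold=scaffold,
                start=start,
                end=start + length,
                repeat_class=classes[int(rng.integers(0, len(classes)))],
            )
        )
        placed += length
    return out


def _build_mitogenome(cfg: SimConfig, rng: np.random.Generator) -> np.ndarray:
    seq = _random_seq(rng, cfg.mt_length)
    base_idx = {b: i for i, b in enumerate("ACGT")}
    for name, start, end, strand in DEFAULT_MT_GENES:
        n_codons = (end - start) // 3
        codons = ["ATG"] + _codons_no_mt_stop(rng, n_codons - 2) + ["TAA"]
        gene = "".join(codons)
        arr = np.array([base_idx[b] for b in gene])
        if strand == MINUS:
            arr = _revcomp_codes(arr)
        seq[start : start + len(arr)] = arr
    return seq


def simulate_dataset(config: SimConfig) -> SimResult:
    """Run the forward simulation; deterministic under ``config.seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    tree = formats.read_tree_string(config.tree_newick)
    layout = _Layout(config)
    orders = _simulate_gene_orders(tree, config, layout, rng)
    events = _draw_events(tree, config, layout, rng)
    carriers = _inherit(tree, events, config, rng)
    truth = _place_copies(tree, events, carriers, orders, config, layout, rng)

    mt_arr = _build_mitogenome(config, rng) if config.emit_sequences else None
    mt_genes = [
        GeneModel(symbol=name, scaffold="MT", start=s, end=e, strand=strand)
        for name, s, e, strand in DEFAULT_MT_GENES
    ]

    data: dict[str, SpeciesData] = {}
    for sp in tree.tips():
        scaffolds = [
            (f"{sp}_scaf{i + 1}", config.scaffold_length)
            for i in range(config.n_scaffolds)
        ]
        index = GenomeIndex(scaffolds)
        genes: list[GeneModel] = []
        for scaf, row in enumerate(orders[sp]):
            for j, sym in enumerate(row):
                start = layout.gene_start(j)
                genes.append(
                    GeneModel(
                        symbol=sym,
                        scaffold=f"{sp}_scaf{scaf + 1}",
                        start=start,
                        end=start + config.gene_length,
                    )
                )
        genes.sort(key=lambda g: (g.scaffold, g.start))
        repeats: list[RepeatInterval] = []
        for name, _ in scaffolds:
            repeats.extend(_simulate_repeats(config, name, rng))
        hsps: list[Hsp] = []
        for ev in truth.events:
            copy = truth.copies[ev.id].get(sp)
            if copy is not None:
                hsps.extend(_copy_to_hsps(ev, copy, config.mt_length))
        hsps.sort(key=lambda h: (h.scaffold, h.n_start))
        seqs: dict[str, str] | None = None
        if config.emit_sequences:
            assert mt_arr is not None
            seq_arrays = {
                name: _random_seq(rng, length) for name, length in scaffolds
            }
            for ev in truth.events:
                copy = truth.copies[ev.id].get(sp)
                if copy is None:
                    continue
                segment = np.concatenate(
                    [mt_arr[s:e] for s, e in ev.mt_intervals]
                ).copy()
                if copy.n_subs:
                    sites = rng.choice(ev.length, size=copy.n_subs, replace=False)
                    shift = rng.integers(1, 4, size=copy.n_subs)
                    segment[sites] = (segment[sites] + shift) % 4
                if copy.orientation == MINUS:
                    segment = _revcomp_codes(segment)
                seq_arrays[copy.scaffold][copy.n_start : copy.n_end] = segment
            seqs = {name: _seq_str(arr) for name, arr in seq_arrays.items()}
        data[sp] = SpeciesData(
            species=sp,
            genome_index=index,
            genes=genes,
            repeats=repeats,
            hsps=hsps,
            genome_seqs=seqs,
        )
    return SimResult(
        config=config,
        tree=tree,
        species=tree.tips(),
        data=data,
        truth=truth,
        mt_genes=mt_genes,
        mitogenome=_seq_str(mt_arr) if mt_arr is not None else None,
    )


def write_dataset(result: SimResult, out_dir: str | Path) -> None:
    """Write the dataset in the pipeline's input formats (text only)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    with open(out / "tree.nwk", "w") as fh:
        fh.write(result.config.tree_newick.strip() + "\n")
    formats.write_repeat_bed(
        out / "mt_genes.bed",
        [
            RepeatInterval(g.scaffold, g.start, g.end, g.symbol)
            for g in result.mt_genes
        ],
    )
    if result.mitogenome is not None:
        formats.write_fasta(out / "mitogenome.fa", [("MT", result.mitogenome)])
    for sp, d in result.data.items():
        spdir = out / sp
        spdir.mkdir(exist_ok=True)
        formats.write_scaffold_lengths(spdir / "scaffolds.tsv", d.genome_index)
        formats.write_gene_gff3(spdir / "genes.gff3", d.genes)
        formats.write_repeat_bed(spdir / "repeats.bed", d.repeats)
        with open(spdir / "hsps.tsv", "w") as fh:
            for h in d.hsps:
                if h.orientation == PLUS:
                    sstart, send = h.n_start + 1, h.n_end
                else:
                    sstart, send = h.n_end, h.n_start + 1
                fh.write(
                    "\t".join(
                        [
                            "MT",
                            h.scaffold,
                            f"{h.identity:.3f}",
                            str(h.aln_length),
                            str(h.mismatches),
                            str(h.gap_opens),
                            str(h.mt_start + 1),
                            str(h.mt_end),
                            str(sstart),
                            str(send),
                            f"{h.e_value:.3g}",
                            f"{h.bit_score:.1f}",
                        ]
                    )
                    + "\n"
                )
        if d.genome_seqs is not None:
            formats.write_fasta(spdir / "genome.fa", sorted(d.genome_seqs.items()))
    truth = {
        "events": [asdict(e) for e in result.truth.events],
        "copies": {
            ev: {sp: asdict(c) for sp, c in sp_copies.items()}
            for ev, sp_copies in result.truth.copies.items()
        },
    }
    with open(out / "truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)


def emit_expression_evidence(
    unit_ids: Sequence[str],
    expressed_fraction: float,
    seed: int,
    tissues: Sequence[str] = ("brain",),
) -> list["ExpressionEvidence"]:
    """Synthetic expression-evidence rows with a designated expressed subset.

    Designated units receive >=2 junction reads on both sides and coverage
    above 0.7 in every tissue; all others fail at least one criterion.
    """
    from .context import ExpressionEvidence

    rng = np.random.default_rng(seed)
    n_expr = int(round(expressed_fraction * len(unit_ids)))
    expressed = set(
        rng.choice(len(unit_ids), size=n_expr, replace=False).tolist()
    )
    rows: list[ExpressionEvidence] = []
    for i, uid in enumerate(unit_ids):
        for tissue in tissues:
            if i in expressed:
                rows.append(
                    ExpressionEvidence(
                        unit_id=uid,
                        tissue=tissue,
                        junction_5=int(rng.integers(2, 11)),
                        junction_3=int(rng.integers(2, 11)),
                        covered_fraction=float(rng.uniform(0.75, 1.0)),
                    )
                )
            else:
                mode = int(rng.integers(0, 3))
                rows.append(
                    ExpressionEvidence(
                        unit_id=uid,
                        tissue=tissue,
                        junction_5=int(rng.integers(0, 2)) if mode != 1 else 3,
                        junction_3=int(rng.integers(0, 2)) if mode != 2 else 3,
                        covered_fraction=float(rng.uniform(0.0, 0.7))
                        if mode != 0
                        else float(rng.uniform(0.71, 1.0)),
                    )
                )
    return rows


def write_expression_evidence(path: str | Path, rows) -> None:
    with open(path, "w") as fh:
        fh.write("unit\ttissue\tjunc5\tjunc3\tcov_fraction\n")
        for r in rows:
            fh.write(
                f"{r.unit_id}\t{r.tissue}\t{r.junction_5}\t{r.junction_3}\t"
                f"{r.covered_fraction:.4f}\n"
            )
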