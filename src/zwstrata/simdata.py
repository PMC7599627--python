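"""Synthetic ZW sex-chromosome data with known ground truth.

Generates every input the analysis stages consume: a colinear Z/W chromosome
pair with planted evolutionary strata, female read-depth tracks, whole-genome
sequencing reads from a genome carrying a query gene at a known copy number,
tissue-by-sex TPM expression matrices with planted female-biased /
ovary-dominant genes, and gametolog CDS sets simulated under shared vs
independent recombination-suppression histories.

All randomness flows from one integer seed; each generator draws from its own
sub-stream (``numpy.random.default_rng([seed, tag])``) so adding a component
never shifts the output of another.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Sequence

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
GAP_CODE = 4  # deleted W position in the colinear frame

# sub-stream tags, one per generator
_TAG_ZW = 1
_TAG_DEPTH = 2
_TAG_READS = 3
_TAG_EXPR = 4
_TAG_GAMETOLOG = 5
_TAG_SCAFFOLDS = 6

TISSUES = ("brain", "heart", "kidney", "liver", "gonad")
SEXES = ("F", "M")


@dataclass(frozen=True)
class StratumSpec:
    """One planted interval on the Z: half-open [start, end) in bp.

    ``divergence`` is the independent per-site probability that the W copy
    differs from Z; ``w_deletion_fraction`` is the expected fraction of the
    interval absent from the W.
    """

    start: int
    end: int
    label: str  # PAR, S0, S1 or S2
    divergence: float = 0.0
    w_deletion_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.end <= self.start or self.start < 0:
            raise ValueError(f"bad stratum interval [{self.start}, {self.end})")
        if not 0.0 <= self.divergence <= 1.0:
            raise ValueError("divergence must be in [0, 1]")
        if not 0.0 <= self.w_deletion_fraction <= 1.0:
            raise ValueError("w_deletion_fraction must be in [0, 1]")


@dataclass(frozen=True)
class GenePlacement:
    gene_id: str
    stratum_label: str
    cds_length: int
    copies_per_haploid: int


@dataclass(frozen=True)
class ExpressionSpec:
    n_genes: int = 200
    baseline_log_tpm_mean: float = 2.0
    baseline_log_tpm_sd: float = 1.0
    female_bias_fraction: float = 0.1
    female_bias_fold: float = 4.0
    ovary_dominant_fraction: float = 0.1
    w_downregulation_factor: float = 0.5
    n_gametolog_pairs: int = 0
    noise_sd: float = 0.0  # multiplicative log-normal noise on every entry


@dataclass
class SimulationConfig:
    seed: int = 0
    z_length: int = 2_000_000
    strata: Sequence[StratumSpec] = field(default_factory=tuple)
    read_length: int = 100
    diploid_depth: float = 50.0
    error_rate: float = 0.0
    gene_placements: Sequence[GenePlacement] = field(default_factory=tuple)
    expression: ExpressionSpec = field(default_factory=ExpressionSpec)

    def __post_init__(self) -> None:
        self.strata = tuple(self.strata)
        prev_end = None
        par_seen = 0
        for s in sorted(self.strata, key=lambda s: s.start):
            if s.end > self.z_length:
                raise ValueError("stratum extends past z_length")
            if prev_end is not None and s.start < prev_end:
                raise ValueError("overlapping strata")
            prev_end = s.end
            if s.label == "PAR":
                par_seen += 1
                if s.start != 0 and s.end != self.z_length:
                    raise ValueError("PAR must sit at a chromosome end")
        if par_seen > 1:
            raise ValueError("at most one PAR interval")
        if sorted(self.strata, key=lambda s: s.start) != list(self.strata):
            self.strata = tuple(sorted(self.strata, key=lambda s: s.start))


@dataclass
class TruthTable:
    """Ground truth emitted alongside every simulated dataset."""

    scaffold_labels: dict[str, str] = field(default_factory=dict)  # A / Z / W
    stratum_intervals: list[tuple[int, int, str, float]] = field(default_factory=list)
    deleted_spans: list[tuple[int, int]] = field(default_factory=list)
    gene_copies: dict[str, int] = field(default_factory=dict)
    female_biased: dict[str, bool] = field(default_factory=dict)
    ovary_dominant: dict[str, bool] = field(default_factory=dict)
    gametolog_pairs: list[tuple[str, str]] = field(default_factory=list)

    def to_json(self) -> str:
        def _default(o):
            if isinstance(o, (np.integer, np.floating)):
                return o.item()
            raise TypeError(f"not JSON serializable: {type(o)}")

        return json.dumps(asdict(self), indent=1, default=_default)


def _rng(seed: int, tag: int) -> np.random.Generator:
    return np.random.default_rng([seed, tag])


def random_sequence(length: int, rng: np.random.Generator) -> np.ndarray:
    """Uniform random base codes 0..3 (A,C,G,T)."""
    return rng.integers(0, 4, size=length, dtype=np.uint8)


def codes_to_str(codes: np.ndarray) -> str:
    out = np.empty(codes.shape, dtype=np.uint8)
    gap = codes == GAP_CODE
    out[~gap] = _BASES[codes[~gap]]
    out[gap] = ord("-")
    return out.tobytes().decode("ascii")


def str_to_codes(seq: str) -> np.ndarray:
    raw = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    lut = np.full(256, GAP_CODE, dtype=np.uint8)
    lut[ord("A")] = 0
    lut[ord("C")] = 1
    lut[ord("G")] = 2
    lut[ord("T")] = 3
    return lut[raw]


def mutate(codes: np.ndarray, p: float, rng: np.random.Generator) -> np.ndarray:
    """Substitute each site with probability p, uniformly over the 3 others."""
    out = codes.copy()
    hit = rng.random(codes.size) < p
    shifts = rng.integers(1, 4, size=int(hit.sum()), dtype=np.uint8)
    out[hit] = (out[hit] + shifts) % 4
    return out


def simulate_zw_pair(config: SimulationConfig) -> tuple[str, str, TruthTable]:
    """Simulate a colinear Z/W chromosome pair with planted strata.

    Returns (z, w, truth) where ``w`` is in the Z coordinate frame: same
    length, with deleted W positions shown as '-'. Within a PAR (or any bp
    not covered by a stratum interval) W is identical to Z; within stratum
    intervals each W site independently differs from Z with the stratum's
    per-site divergence, and ``w_deletion_fraction`` of the interval is
    removed (sampled as 1-kb tiles, recorded as merged spans in the truth).
    """
    rng = _rng(config.seed, _TAG_ZW)
    z = random_sequence(config.z_length, rng)
    w = z.copy()
    truth = TruthTable()
    for s in config.strata:
        seg = slice(s.start, s.end)
        w[seg] = mutate(z[seg], s.divergence, rng)
        truth.stratum_intervals.append((s.start, s.end, s.label, s.divergence))
        if s.w_deletion_fraction > 0:
            tile = 1000
            starts = np.arange(s.start, s.end, tile)
            drop = rng.random(starts.size) < s.w_deletion_fraction
            spans: list[tuple[int, int]] = []
            for t0 in starts[drop].tolist():
                t1 = min(t0 + tile, s.end)
                w[t0:t1] = GAP_CODE
                if spans and spans[-1][1] == t0:
                    spans[-1] = (spans[-1][0], t1)
                else:
                    spans.append((int(t0), int(t1)))
            truth.deleted_spans.extend(spans)
    return codes_to_str(z), codes_to_str(w), truth


@dataclass
class SimulatedScaffold:
    scaffold_id: str
    label: str  # A, Z or W
    length: int
    depth: np.ndarray  # per-base, 1-based positions 1..length
    z_aligned_blocks: list[tuple[int, int]]  # 0-based half-open on the scaffold

    @property
    def z_aligned_fraction(self) -> float:
        return sum(e - s for s, e in self.z_aligned_blocks) / self.length


def simulate_depth_track(
    config: SimulationConfig, labels: dict[str, str], lengths: dict[str, int]
) -> dict[str, np.ndarray]:
    """Female per-base Poisson depth per scaffold.

    Autosomes (and PAR) sit at the diploid depth; W and differentiated-Z
    scaffolds at half of it (one copy in a ZW female).
    """
    rng = _rng(config.seed, _TAG_DEPTH)
    tracks = {}
    for sid in labels:
        mean = config.diploid_depth if labels[sid] == "A" else config.diploid_depth / 2.0
        tracks[sid] = rng.poisson(mean, size=lengths[sid]).astype(np.int64)
    return tracks


def simulate_scaffold_genome(
    config: SimulationConfig,
    n_scaffolds: int = 100,
    scaffold_length: int = 200_000,
    fractions: tuple[float, float, float] = (0.70, 0.15, 0.15),
) -> tuple[list[SimulatedScaffold], TruthTable]:
    """A fragmented female genome: autosomal, Z-linked and W-linked scaffolds.

    Z scaffolds carry alignment blocks to the reference Z covering >60% of
    their length; autosomes and W candidates align only sporadically (<40%).
    Depth tracks follow simulate_depth_track's half-coverage rule.
    """
    rng = _rng(config.seed, _TAG_SCAFFOLDS)
    n_a = int(round(fractions[0] * n_scaffolds))
    n_z = int(round(fractions[1] * n_scaffolds))
    n_w = n_scaffolds - n_a - n_z
    labels = ["A"] * n_a + ["Z"] * n_z + ["W"] * n_w
    truth = TruthTable()
    scaffolds = []
    label_map = {}
    lengths = {}
    for i, lab in enumerate(labels):
        sid = f"scaf{i:03d}"
        label_map[sid] = lab
        lengths[sid] = scaffold_length
        truth.scaffold_labels[sid] = lab
    tracks = simulate_depth_track(config, label_map, lengths)
    for i, lab in enumerate(labels):
        sid = f"scaf{i:03d}"
        if lab == "Z":
            frac = rng.uniform(0.65, 0.95)
        elif lab == "W":
            frac = rng.uniform(0.05, 0.40)
        else:
            frac = rng.uniform(0.0, 0.10)
        span = int(frac * scaffold_length)
        start = int(rng.integers(0, scaffold_length - span + 1)) if span else 0
        blocks = [(start, start + span)] if span else []
        scaffolds.append(
            SimulatedScaffold(sid, lab, scaffold_length, tracks[sid], blocks)
        )
    return scaffolds, truth


def insert_gene_copies(
    background: np.ndarray, cds: np.ndarray, copies: int, rng: np.random.Generator
) -> np.ndarray:
    """Insert `copies` tandem-free copies of a CDS at random positions."""
    if copies == 0:
        return background
    pieces = []
    cuts = np.sort(rng.integers(0, background.size, size=copies))
    prev = 0
    for cut in cuts:
        pieces.append(background[prev:cut])
        pieces.append(cds)
        prev = cut
    pieces.append(background[prev:])
    return np.concatenate(pieces)


def simulate_reads(
    genome: np.ndarray | str | Sequence, config: SimulationConfig
) -> list[str]:
    """Whole-genome shotgun reads: uniform starts, fixed length, iid errors.

    ``genome`` is either one sequence (sequenced as two identical
    haplotypes) or a list of haplotype sequences sampled equally, each at
    diploid_depth / n_haplotypes fold coverage of its own length — so a
    hemizygous locus (present on one haplotype only, like the W) gets half
    the depth of shared sequence.
    """
    if isinstance(genome, str) or isinstance(genome, np.ndarray):
        haplotypes = [genome, genome]
    else:
        haplotypes = list(genome)
    haplotypes = [str_to_codes(h) if isinstance(h, str) else h for h in haplotypes]
    rng = _rng(config.seed, _TAG_READS)
    depth_per_hap = config.diploid_depth / len(haplotypes)
    L = config.read_length
    reads: list[str] = []
    for hap in haplotypes:
        glen = hap.size
        if L > glen:
            raise ValueError("read_length exceeds genome length")
        n_reads = int(round(depth_per_hap * glen / L))
        starts = rng.integers(0, glen - L + 1, size=n_reads)
        for s in starts:
            r = hap[s : s + L]
            if config.error_rate > 0:
                r = mutate(r, config.error_rate, rng)
            reads.append(codes_to_str(r))
    return reads


def simulate_gene_copy_dataset(
    config: SimulationConfig, background_length: int = 1_000_000
) -> tuple[list[str], dict[str, str], TruthTable]:
    """Reads from a diploid carrying each configured gene at N copies,
    hemizygously (on one haplotype only, the W-linked situation).

    The background is shared by both haplotypes, so its k-mers sit at the
    diploid depth while each planted gene copy contributes one haploid
    unit. Returns (reads, cds_by_gene, truth). CDS sequences are drawn
    fresh so their k-mers are (with overwhelming probability) absent from
    the background except where planted.
    """
    rng = _rng(config.seed, _TAG_READS + 100)
    background = random_sequence(background_length, rng)
    truth = TruthTable()
    cds_by_gene: dict[str, str] = {}
    carrier = background
    for gp in config.gene_placements:
        cds = random_sequence(gp.cds_length, rng)
        cds_by_gene[gp.gene_id] = codes_to_str(cds)
        truth.gene_copies[gp.gene_id] = gp.copies_per_haploid
        carrier = insert_gene_copies(carrier, cds, gp.copies_per_haploid, rng)
    reads = simulate_reads([carrier, background], config)
    return reads, cds_by_gene, truth


def simulate_expression(config: SimulationConfig):
    """Tissue x sex TPM matrix with planted truth.

    Baseline TPM is log-normal. Planted female-biased genes have all female
    columns multiplied by ``female_bias_fold``; planted ovary-dominant genes
    have gonad_F inflated to equal the sum of the other nine tissue-sex
    values (ratio 0.5, comfortably above the 20% dominance rule). Gametolog
    pairs append a W row per chosen Z row: zero in males,
    ``w_downregulation_factor`` x the Z female values in females.

    Returns (DataFrame genes x tissue_sex columns, TruthTable).
    """
    import pandas as pd

    spec = config.expression
    rng = _rng(config.seed, _TAG_EXPR)
    cols = [f"{t}_{s}" for t in TISSUES for s in SEXES]
    n = spec.n_genes
    base = rng.lognormal(spec.baseline_log_tpm_mean, spec.baseline_log_tpm_sd, size=(n, 1))
    tissue_effect = rng.lognormal(0.0, 0.3, size=(n, len(cols)))
    tpm = base * tissue_effect
    if spec.noise_sd > 0:
        tpm = tpm * rng.lognormal(0.0, spec.noise_sd, size=tpm.shape)
    genes = [f"gene{i:04d}" for i in range(n)]
    truth = TruthTable()
    n_fb = int(round(spec.female_bias_fraction * n))
    n_ov = int(round(spec.ovary_dominant_fraction * n))
    idx = rng.permutation(n)
    fb_idx = set(idx[:n_fb].tolist())
    ov_idx = set(idx[n_fb : n_fb + n_ov].tolist())
    female_cols = [j for j, c in enumerate(cols) if c.endswith("_F")]
    ovary_col = cols.index("gonad_F")
    other_cols = [j for j in range(len(cols)) if j != ovary_col]
    for i in range(n):
        truth.female_biased[genes[i]] = i in fb_idx
        truth.ovary_dominant[genes[i]] = i in ov_idx
        if i in fb_idx:
            tpm[i, female_cols] *= spec.female_bias_fold
        if i in ov_idx:
            tpm[i, ovary_col] = tpm[i, other_cols].sum()
    df = pd.DataFrame(tpm, index=genes, columns=cols)
    if spec.n_gametolog_pairs > 0:
        z_rows = [genes[i] for i in idx[-spec.n_gametolog_pairs :]]
        w_data = {}
        for zg in z_rows:
            wg = zg + "_W"
            row = df.loc[zg].copy()
            for c in cols:
                if c.endswith("_M"):
                    row[c] = 0.0
                else:
                    row[c] = row[c] * spec.w_downregulation_factor
            w_data[wg] = row
            truth.gametolog_pairs.append((zg, wg))
        df = pd.concat([df, pd.DataFrame(w_data).T])
    return df, truth


def simulate_gametologs(
    seed: int,
    cds_length: int = 3000,
    n_species: int = 3,
    shared: bool = True,
    d_old: float = 0.10,
    d_recent: float = 0.02,
    with_outgroup: bool = False,
) -> dict[tuple[str, str], str]:
    """Gametolog CDS set under a shared or independent stratum origin.

    shared=True: Z/W recombination stopped once in the common ancestor
    (branch divergence ``d_old`` on each side), then species split (each
    terminal accumulates ``d_recent``) — W copies cluster together.
    shared=False: species split first (``d_old`` per lineage), then Z/W
    stopped recombining independently within each species (``d_recent`` per
    copy) — each species' Z+W pair clusters.

    Returns {(species, 'Z'|'W'): ungapped sequence}; sequences share the
    coordinate frame (no indels) so they are already aligned.
    """
    rng = _rng(seed, _TAG_GAMETOLOG)
    root = random_sequence(cds_length, rng)
    out: dict[tuple[str, str], str] = {}
    species = [f"sp{i + 1}" for i in range(n_species)]
    if shared:
        anc_z = mutate(root, d_old, rng)
        anc_w = mutate(root, d_old, rng)
        for sp in species:
            out[(sp, "Z")] = codes_to_str(mutate(anc_z, d_recent, rng))
            out[(sp, "W")] = codes_to_str(mutate(anc_w, d_recent, rng))
    else:
        for sp in species:
            anc = mutate(root, d_old, rng)
            out[(sp, "Z")] = codes_to_str(mutate(anc, d_recent, rng))
            out[(sp, "W")] = codes_to_str(mutate(anc, d_recent, rng))
    if with_outgroup:
        out[("outgroup", "Z")] = codes_to_str(mutate(root, 2.5 * d_old, rng))
    return out


def strip_gaps(w_colinear: str) -> str:
    """The W sequence as it would appear in a FASTA: deletions omitted."""
    return w_colinear.replace("-", "")
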