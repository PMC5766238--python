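"""Synthetic genomes, annotations, PWMs and expression with planted truth.

Every downstream stage (region derivation, feature computation, lasso
modelling, stability selection, error trees, TAD statistics) is testable
against this generator without any external download:

* genomes are drawn i.i.d. per nucleotide from a configurable base
  composition; a TAD-level dinucleotide shift is realised through a
  first-order Markov chain, giving direct control over dinucleotide
  percentages;
* each gene carries a full annotation (5'UTR, CDS, 3'UTR, introns and one
  or more TSSs), placed without overlap with one synthetic chromosome per
  TAD plus one chromosome for TAD-free genes;
* expression follows the same sparse linear model the pipeline fits:
  ``y(g) = a + sum_i b_i x~_{i,g} + e(g)`` with standardized features
  ``x~``, Gaussian noise, and independent noise per sample.  Expression is
  emitted on the already-log scale, so the pipeline's log transform is
  meant for count-like real data only.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .features import DINUCLEOTIDES, NUCLEOTIDES, SHAPE_NAMES, kmer_label
from .intervals import GenomicInterval
from .io import GtfRecord
from .regions import REGION_KINDS, GeneModel

_GENE_GAP = 3500
_CHROM_PAD = 2500

_VARIABLE_RE = re.compile(
    r"^(?P<feature>.+)_(?P<region>" + "|".join(REGION_KINDS) + r")$"
)


class ConfigurationError(ValueError):
    pass


@dataclass
class SimulationConfig:
    n_genes: int = 2000
    n_samples: int = 1
    region_length_means: dict[str, int] = field(
        default_factory=lambda: {"UTR5": 300, "CDS": 1500, "UTR3": 900, "INTR": 3000}
    )
    n_tss_range: tuple[int, int] = (1, 4)
    tad_count: int = 0
    genes_per_tad: int = 0
    planted_support: list[tuple[str, float]] = field(default_factory=list)
    noise_sd: float = 1.0
    intercept: float = 0.0
    base_composition: dict[str, float] = field(
        default_factory=lambda: {n: 0.25 for n in NUCLEOTIDES}
    )
    tad_shift: dict[tuple[str, str], float] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        probs = [self.base_composition.get(n, 0.0) for n in NUCLEOTIDES]
        if abs(sum(probs) - 1.0) > 1e-12 or any(p < 0 for p in probs):
            raise ConfigurationError("base_composition must be non-negative and sum to 1")
        for name, _ in self.planted_support:
            if not _VARIABLE_RE.match(name):
                raise ConfigurationError(
                    f"planted variable {name!r} does not parse as <feature>_<REGION> "
                    f"with REGION in {REGION_KINDS}"
                )
        if self.n_tss_range[0] < 1 or self.n_tss_range[0] > self.n_tss_range[1]:
            raise ConfigurationError("n_tss_range must satisfy 1 <= min <= max")
        for kind, mean in self.region_length_means.items():
            if mean < 1:
                raise ConfigurationError(f"region_length_means[{kind!r}] must be >= 1")
        if self.tad_count * self.genes_per_tad > self.n_genes:
            raise ConfigurationError(
                "tad_count * genes_per_tad exceeds n_genes: "
                f"{self.tad_count} * {self.genes_per_tad} > {self.n_genes}"
            )


@dataclass
class GroundTruth:
    true_beta: dict[str, float]
    true_intercept: float
    tad_assignments: dict[str, str]
    shifted_tads: set[str]


@dataclass
class SyntheticAnnotation:
    genome: dict[str, str]
    genes: list[GeneModel]
    gtf_records: list[GtfRecord]
    tads: dict[str, GenomicInterval]
    tad_assignments: dict[str, str]


# ---------------------------------------------------------------------------
# sequence sampling


def transition_matrix(
    base_composition: dict[str, float], shifts: dict[str, float] | None = None
) -> np.ndarray:
    """First-order transition matrix realising additive dinucleotide shifts.

    Without shifts every row equals the base composition (i.i.d. letters).
    A shift ``s`` on dinucleotide NpM raises the NpM frequency by about
    ``s`` (in probability units) by adding ``s / P(N)`` to the N -> M
    transition and rescaling the other transitions of row N.
    """
    p = np.array([base_composition[n] for n in NUCLEOTIDES])
    T = np.tile(p, (4, 1))
    if shifts:
        adjust: dict[int, dict[int, float]] = {}
        for dinuc, s in shifts.items():
            pair = dinuc.replace("p", "")
            if len(pair) != 2 or any(b not in NUCLEOTIDES for b in pair):
                raise ConfigurationError(f"bad dinucleotide in tad_shift: {dinuc!r}")
            i, j = NUCLEOTIDES.index(pair[0]), NUCLEOTIDES.index(pair[1])
            adjust.setdefault(i, {})[j] = s
        for i, targets in adjust.items():
            row = T[i].copy()
            for j, s in targets.items():
                if p[i] <= 0:
                    raise ConfigurationError(f"cannot shift from zero-probability base {NUCLEOTIDES[i]}")
                row[j] = min(max(row[j] + s / p[i], 1e-6), 0.95)
            fixed = list(targets)
            free = [j for j in range(4) if j not in fixed]
            residual = 1.0 - row[fixed].sum()
            if residual <= 0 or T[i][free].sum() <= 0:
                raise ConfigurationError("tad_shift too large: transition row degenerate")
            row[free] = T[i][free] * residual / T[i][free].sum()
            T[i] = row
    return T


def sample_sequence(
    length: int,
    base_composition: dict[str, float],
    rng: np.random.Generator,
    shifts: dict[str, float] | None = None,
) -> str:
    """Draw one sequence; i.i.d. unless dinucleotide shifts request a Markov chain."""
    p = np.array([base_composition[n] for n in NUCLEOTIDES])
    letter_bytes = np.frombuffer(b"ACGT", dtype=np.uint8)
    if not shifts:
        idx = np.searchsorted(np.cumsum(p), rng.random(length), side="right")
        return letter_bytes[np.minimum(idx, 3)].tobytes().decode("ascii")
    T = transition_matrix(base_composition, shifts)
    cum = np.cumsum(T, axis=1)
    u = rng.random(length)
    out = np.empty(length, dtype=np.int64)
    out[0] = min(int(np.searchsorted(np.cumsum(p), u[0], side="right")), 3)
    for i in range(1, length):
        out[i] = min(int(np.searchsorted(cum[out[i - 1]], u[i], side="right")), 3)
    return letter_bytes[out].tobytes().decode("ascii")


def simulate_composition_features(
    n_genes: int,
    seq_length: int,
    base_composition: dict[str, float],
    shifted_genes: set[str] | None = None,
    shifts: dict[str, float] | None = None,
    seed: int = 0,
    region: str = "INTR",
) -> pd.DataFrame:
    """Per-gene composition percentages of one region, sequences drawn directly.

    A lighter-weight route than generating a full annotation: each gene gets
    one region-length sequence (Markov-shifted for ``shifted_genes``) and its
    4 nucleotide + 16 dinucleotide percentages.  Used for cohort-scale
    composition experiments such as TAD signature power studies.
    """
    from .features import kmer_percentage, nt_percentage

    rng = np.random.default_rng([seed, 505])
    shifted_genes = shifted_genes or set()
    rows = {}
    for i in range(n_genes):
        gid = f"G{i:05d}"
        gene_shifts = shifts if gid in shifted_genes else None
        seq = sample_sequence(seq_length, base_composition, rng, gene_shifts)
        vals = {f"{n}_{region}": v for n, v in nt_percentage(seq).items()}
        vals.update({f"{k}_{region}": v for k, v in kmer_percentage(seq, 2).items()})
        rows[gid] = vals
    return pd.DataFrame.from_dict(rows, orient="index")


# ---------------------------------------------------------------------------
# annotation generation


def _gene_layout(config: SimulationConfig, rng: np.random.Generator) -> dict[str, int]:
    """Draw region lengths around their configured means (uniform +/- 40%)."""
    out = {}
    for kind in ("UTR5", "CDS", "UTR3", "INTR"):
        mean = config.region_length_means[kind]
        out[kind] = max(20, int(rng.uniform(0.6, 1.4) * mean))
    return out


def generate_annotation(config: SimulationConfig) -> SyntheticAnnotation:
    """Generate the genome, gene models, GTF records and TAD intervals.

    Genes are laid out without overlap, one synthetic chromosome per TAD
    (its genes are contiguous within the TAD interval) plus one chromosome
    for TAD-free genes.  Deterministic for a fixed config seed.
    """
    rng = np.random.default_rng([config.seed, 101])
    genome: dict[str, str] = {}
    genes: list[GeneModel] = []
    gtf_records: list[GtfRecord] = []
    tads: dict[str, GenomicInterval] = {}
    tad_assignments: dict[str, str] = {}

    plan: list[tuple[str, str | None, int]] = []  # (chrom, tad_id, n_genes)
    for t in range(config.tad_count):
        plan.append((f"chrT{t + 1}", f"tad{t + 1}", config.genes_per_tad))
    n_free = config.n_genes - config.tad_count * config.genes_per_tad
    if n_free > 0:
        plan.append(("chrFree", None, n_free))

    gene_counter = 0
    for chrom, tad_id, n_chrom_genes in plan:
        shifts = {
            dinuc: s
            for (tid, dinuc), s in config.tad_shift.items()
            if tid == tad_id and tad_id is not None
        }
        cursor = _CHROM_PAD
        chrom_genes: list[GeneModel] = []
        for _ in range(n_chrom_genes):
            gene_counter += 1
            gid = f"G{gene_counter:05d}"
            layout = _gene_layout(config, rng)
            strand = "+" if rng.random() < 0.5 else "-"
            model, records = _build_gene(gid, chrom, strand, cursor, layout, config, rng)
            genes.append(model)
            chrom_genes.append(model)
            gtf_records.extend(records)
            if tad_id is not None:
                tad_assignments[gid] = tad_id
            cursor = model.end + _GENE_GAP
        chrom_len = cursor - _GENE_GAP + _CHROM_PAD
        genome[chrom] = sample_sequence(
            chrom_len, config.base_composition, rng, shifts or None
        )
        if tad_id is not None:
            tads[tad_id] = GenomicInterval(
                chrom,
                max(0, chrom_genes[0].start - 100),
                chrom_genes[-1].end + 100,
            )
    return SyntheticAnnotation(
        genome=genome,
        genes=genes,
        gtf_records=gtf_records,
        tads=tads,
        tad_assignments=tad_assignments,
    )


def _build_gene(
    gid: str,
    chrom: str,
    strand: str,
    start: int,
    layout: dict[str, int],
    config: SimulationConfig,
    rng: np.random.Generator,
) -> tuple[GeneModel, list[GtfRecord]]:
    l5, lc, l3 = layout["UTR5"], layout["CDS"], layout["UTR3"]
    i1 = layout["INTR"] // 2
    i2 = layout["INTR"] - i1
    # transcription-coordinate segments: [UTR5][intron1][CDS][intron2][UTR3]
    segs = {
        "UTR5": (0, l5),
        "intron1": (l5, l5 + i1),
        "CDS": (l5 + i1, l5 + i1 + lc),
        "intron2": (l5 + i1 + lc, l5 + i1 + lc + i2),
        "UTR3": (l5 + i1 + lc + i2, l5 + i1 + lc + i2 + l3),
    }
    L = l5 + i1 + lc + i2 + l3
    end = start + L

    def to_genomic(a: int, b: int) -> tuple[int, int]:
        if strand == "+":
            return start + a, start + b
        return end - b, end - a

    n_tss = int(rng.integers(config.n_tss_range[0], config.n_tss_range[1] + 1))
    offsets = [0]
    if n_tss > 1 and l5 > 40:
        extra = sorted(rng.integers(20, max(21, l5 - 10), size=n_tss - 1).tolist())
        offsets += extra
    # transcription order = increasing offset from the gene 5' end
    tss_list = [start + off if strand == "+" else end - 1 - off for off in offsets]

    records = [
        GtfRecord(chrom, "synthetic", "gene", start, end, strand, {"gene_id": gid})
    ]
    utr5_ivs, cds_ivs, utr3_ivs = [], [], []
    for t_idx, off in enumerate(offsets):
        tid = f"{gid}.t{t_idx + 1}"
        attrs = {"gene_id": gid, "transcript_id": tid}
        tg_start, tg_end = to_genomic(off, L)
        records.append(
            GtfRecord(chrom, "synthetic", "transcript", tg_start, tg_end, strand, attrs)
        )
        feature_of = {"UTR5": "five_prime_utr", "CDS": "CDS", "UTR3": "three_prime_utr"}
        for seg, feature in feature_of.items():
            a, b = segs[seg]
            a = max(a, off)
            if a >= b:
                continue
            gs, ge = to_genomic(a, b)
            records.append(GtfRecord(chrom, "synthetic", feature, gs, ge, strand, attrs))
            records.append(GtfRecord(chrom, "synthetic", "exon", gs, ge, strand, attrs))
            iv = GenomicInterval(chrom, gs, ge, strand)
            {"UTR5": utr5_ivs, "CDS": cds_ivs, "UTR3": utr3_ivs}[seg].append(iv)

    model = GeneModel(
        gene_id=gid,
        chrom=chrom,
        strand=strand,
        start=start,
        end=end,
        tss_list=tss_list,
        utr5=utr5_ivs,
        cds=cds_ivs,
        utr3=utr3_ivs,
    )
    return model, records


# ---------------------------------------------------------------------------
# expression simulation


def simulate_expression(
    features: pd.DataFrame,
    config: SimulationConfig,
    tad_assignments: dict[str, str] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Expression from the planted sparse linear model plus Gaussian noise.

    ``y(g) = a + sum_i b_i x~_{i,g} + e(g)`` per sample, where ``x~`` is
    the feature standardized across genes and ``e ~ N(0, noise_sd^2)``
    independently per gene and sample.
    """
    missing = [name for name, _ in config.planted_support if name not in features.columns]
    if missing:
        raise ConfigurationError(f"planted variables missing from features: {missing}")
    rng = np.random.default_rng([config.seed, 202])
    n = len(features)
    signal = np.zeros(n)
    true_beta: dict[str, float] = {}
    for name, coef in config.planted_support:
        x = features[name].to_numpy(dtype=float)
        sd = x.std()
        if sd == 0:
            raise ConfigurationError(f"planted variable {name} has zero variance")
        signal += coef * (x - x.mean()) / sd
        true_beta[name] = true_beta.get(name, 0.0) + coef
    samples = [f"S{i + 1}" for i in range(config.n_samples)]
    noise = rng.normal(0.0, config.noise_sd, size=(n, config.n_samples))
    y = config.intercept + signal[:, None] + noise
    expression = pd.DataFrame(y, index=features.index, columns=samples)
    truth = GroundTruth(
        true_beta=true_beta,
        true_intercept=config.intercept,
        tad_assignments=dict(tad_assignments or {}),
        shifted_tads={tid for (tid, _), s in config.tad_shift.items() if s != 0},
    )
    return expression, truth


# ---------------------------------------------------------------------------
# PWMs and shape tables


def generate_pwms(
    n_motifs: int,
    length_range: tuple[int, int] = (6, 12),
    seed: int = 0,
    concentration: float = 0.5,
) -> dict[str, np.ndarray]:
    """Random PFM count matrices (JASPAR-writable), Dirichlet-drawn columns."""
    if length_range[0] < 2:
        raise ValueError("motif length must be >= 2")
    rng = np.random.default_rng([seed, 303])
    motifs: dict[str, np.ndarray] = {}
    for m in range(n_motifs):
        length = int(rng.integers(length_range[0], length_range[1] + 1))
        probs = rng.dirichlet(np.full(4, concentration), size=length).T  # (4, L)
        counts = np.round(probs * 100)
        motifs[f"SYN{m + 1:04d}"] = counts
    return motifs


def generate_shape_table(seed: int = 0) -> pd.DataFrame:
    """A synthetic pentamer shape table covering all 1024 pentamers.

    Values are Gaussian around typical scales of the four shape
    parameters; this is a synthetic stand-in table with the same layout as
    experimentally derived pentamer tables, not a physical model.
    """
    import itertools

    rng = np.random.default_rng([seed, 404])
    pentamers = ["".join(p) for p in itertools.product(NUCLEOTIDES, repeat=5)]
    scales = {"MGW": (5.0, 0.5), "HelT": (34.0, 1.5), "ProT": (-7.0, 3.0), "Roll": (0.0, 3.0)}
    data = {"pentamer": pentamers}
    for name in SHAPE_NAMES:
        mu, sd = scales[name]
        data[name] = rng.normal(mu, sd, size=len(pentamers))
    return pd.DataFrame(data)


def feature_names(regions=REGION_KINDS) -> list[str]:
    """The 20 composition variable names per region, in canonical order."""
    names = []
    for region in regions:
        names += [f"{n}_{region}" for n in NUCLEOTIDES]
        names += [f"{kmer_label(d)}_{region}" for d in DINUCLEOTIDES]
    return names
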