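"""Predictive variables computed from region sequences.

Three feature families are supported, assembled into a genes x variables
matrix (a :class:`pandas.DataFrame` whose columns are named
``<feature>_<REGION>``, e.g. ``CpG_CORE``):

* nucleotide / k-mer percentages: ``100 * #N / l`` for single nucleotides
  and ``100 * #kmer / (l - k + 1)`` for k-mers, with windows containing
  ambiguous bases excluded from both numerator and denominator;
* PWM motif scores: log-odds of a position weight matrix against a
  background prior, summarised per sequence as the maximum (or the sum)
  over all scan positions;
* DNA-shape scores: per-sequence means of pentamer-table values for minor
  groove width (MGW), helix twist (HelT), propeller twist (ProT) and Roll.

Empty or all-ambiguous sequences are missing-coded (NaN), never zero.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .regions import REGION_KINDS, RegionCatalog, reverse_complement

logger = logging.getLogger(__name__)

NUCLEOTIDES = ("A", "C", "G", "T")
DINUCLEOTIDES = tuple(a + b for a in NUCLEOTIDES for b in NUCLEOTIDES)
SHAPE_NAMES = ("MGW", "HelT", "ProT", "Roll")

_ENCODE = {"A": 0, "C": 1, "G": 2, "T": 3}


def kmer_label(kmer: str) -> str:
    """Field naming: dinucleotides as ``NpM``, other k-mers verbatim."""
    return "p".join(kmer) if len(kmer) == 2 else kmer


def _encode(seq: str) -> np.ndarray:
    """Map a sequence to integers 0-3, ambiguous bases to -1."""
    arr = np.frombuffer(seq.upper().encode("ascii"), dtype=np.uint8)
    out = np.full(arr.shape, -1, dtype=np.int64)
    for base, code in _ENCODE.items():
        out[arr == ord(base)] = code
    return out


# ---------------------------------------------------------------------------
# composition percentages


def nt_percentage(seq: str) -> dict[str, float] | None:
    """Percentage of each nucleotide among the unambiguous bases of ``seq``."""
    idx = _encode(seq)
    valid = idx[idx >= 0]
    if valid.size == 0:
        logger.warning("sequence has no unambiguous bases; missing-coded")
        return None
    counts = np.bincount(valid, minlength=4)
    return {n: 100.0 * counts[i] / valid.size for i, n in enumerate(NUCLEOTIDES)}


def kmer_percentage(seq: str, k: int) -> dict[str, float] | None:
    """Percentage of each k-mer among the valid length-k windows of ``seq``.

    The denominator is the number of windows free of ambiguous bases
    (``l - k + 1`` for a clean sequence), matching the ``#NpM / (l - 1)``
    dinucleotide convention.
    """
    idx = _encode(seq)
    if idx.size < k:
        return None
    windows = np.lib.stride_tricks.sliding_window_view(idx, k)
    valid = windows[(windows >= 0).all(axis=1)]
    if valid.shape[0] == 0:
        logger.warning("sequence has no unambiguous %d-mer window; missing-coded", k)
        return None
    codes = valid @ (4 ** np.arange(k - 1, -1, -1))
    counts = np.bincount(codes, minlength=4**k)
    kmers = ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=k))
    return {
        kmer_label(kmer): 100.0 * counts[i] / valid.shape[0]
        for i, kmer in enumerate(kmers)
    }


def double_strand_groups(k: int = 2) -> dict[str, tuple[str, ...]]:
    """Reverse-complement equivalence classes of k-mers.

    For dinucleotides this yields the 10 unique duplex steps (6 pairs plus
    the 4 self-reverse-complementary dinucleotides ApT, TpA, CpG, GpC);
    for single nucleotides the 2 base pairs A|T and C|G.
    """
    groups: dict[str, tuple[str, ...]] = {}
    seen: set[str] = set()
    for kmer in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=k)):
        if kmer in seen:
            continue
        rc = reverse_complement(kmer)
        members = (kmer,) if rc == kmer else (kmer, rc)
        seen.update(members)
        name = "|".join(kmer_label(m) for m in members)
        groups[name] = members
    return groups


def collapse_double_strand(features: pd.DataFrame) -> pd.DataFrame:
    """Merge single-strand composition columns into duplex (dsDNA) features.

    Each reverse-complement pair of columns (per region) is summed;
    self-reverse-complementary k-mers pass through under their own name.
    The groups partition the input percentages, so row sums are conserved.
    """
    out: dict[str, pd.Series] = {}
    consumed: set[str] = set()
    groups = {**double_strand_groups(1), **double_strand_groups(2)}
    for region in REGION_KINDS:
        for name, members in groups.items():
            cols = [f"{kmer_label(m)}_{region}" for m in members]
            present = [c for c in cols if c in features.columns]
            if not present:
                continue
            if len(present) != len(cols):
                raise ValueError(
                    f"cannot collapse {name}_{region}: columns {cols} incomplete"
                )
            label = name if len(members) == 1 else name
            out[f"{label}_{region}"] = features[present].sum(axis=1, min_count=len(present))
            consumed.update(present)
    passthrough = [c for c in features.columns if c not in consumed]
    result = pd.DataFrame(out, index=features.index)
    if passthrough:
        result = pd.concat([result, features[passthrough]], axis=1)
    return result


# ---------------------------------------------------------------------------
# PWM motif scores


@dataclass
class PWM:
    """A position weight matrix with strictly positive column probabilities."""

    motif_id: str
    probs: np.ndarray  # shape (4, length), columns sum to 1
    prior: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=float)
        self.prior = np.asarray(self.prior, dtype=float)
        if self.probs.shape[0] != 4:
            raise ValueError("PWM needs 4 rows (A, C, G, T)")
        if not np.allclose(self.probs.sum(axis=0), 1.0, atol=1e-9):
            raise ValueError("PWM columns must sum to 1")
        if not math.isclose(self.prior.sum(), 1.0, abs_tol=1e-9):
            raise ValueError("prior must sum to 1")
        if (self.probs <= 0).any() or (self.prior <= 0).any():
            raise ValueError("PWM probabilities must be strictly positive")

    def __len__(self) -> int:
        return self.probs.shape[1]

    @property
    def log_odds(self) -> np.ndarray:
        return np.log(self.probs) - np.log(self.prior)[:, None]

    def with_prior(self, prior: np.ndarray) -> "PWM":
        return PWM(self.motif_id, self.probs, np.asarray(prior, dtype=float))


def pwm_from_counts(
    motif_id: str,
    counts: np.ndarray,
    pseudocount: float = 1e-3,
    prior: np.ndarray | None = None,
) -> PWM:
    """Normalize a count (PFM) matrix into probabilities with a pseudocount."""
    counts = np.asarray(counts, dtype=float)
    col_sums = counts.sum(axis=0)
    probs = (counts / np.where(col_sums > 0, col_sums, 1.0)) + pseudocount
    probs /= probs.sum(axis=0)
    return PWM(motif_id, probs, prior if prior is not None else np.full(4, 0.25))


def _window_scores(pwm: PWM, idx: np.ndarray) -> np.ndarray:
    """Log-odds score of every valid window; invalid windows are NaN."""
    L = len(pwm)
    if idx.size < L:
        return np.empty(0)
    windows = np.lib.stride_tricks.sliding_window_view(idx, L)
    valid = (windows >= 0).all(axis=1)
    scores = np.full(windows.shape[0], np.nan)
    if valid.any():
        lo = pwm.log_odds
        scores[valid] = lo[windows[valid], np.arange(L)].sum(axis=1)
    return scores


def pwm_score_at(pwm: PWM, seq: str, i: int) -> float:
    """Score of the motif at position ``i``: sum_j log(P(s_{i+j}|w_j)/P(s_{i+j}))."""
    idx = _encode(seq)
    if i < 0 or i > idx.size - len(pwm):
        raise ValueError(f"position {i} outside [0, {idx.size - len(pwm)}]")
    window = idx[i : i + len(pwm)]
    if (window < 0).any():
        raise ValueError(f"window at {i} contains ambiguous bases")
    lo = pwm.log_odds
    return float(lo[window, np.arange(len(pwm))].sum())


def pwm_score_max(pwm: PWM, seq: str, both_strands: bool = False) -> float:
    """Maximum window score over the sequence (ties go to the smallest i)."""
    scores = _scan(pwm, seq, both_strands)
    if scores.size == 0 or np.isnan(scores).all():
        return float("nan")
    return float(np.nanmax(scores))


def pwm_score_sum(pwm: PWM, seq: str, both_strands: bool = False) -> float:
    """Sum of window scores over the sequence."""
    scores = _scan(pwm, seq, both_strands)
    if scores.size == 0 or np.isnan(scores).all():
        return float("nan")
    return float(np.nansum(scores))


def _scan(pwm: PWM, seq: str, both_strands: bool) -> np.ndarray:
    scores = _window_scores(pwm, _encode(seq))
    if both_strands:
        rc = _window_scores(pwm, _encode(reverse_complement(seq)))
        if rc.size == scores.size:
            scores = np.fmax(scores, rc[::-1])
    return scores


def scanned_prior(sequences: Iterable[str]) -> np.ndarray:
    """Background nucleotide probabilities pooled over all scanned sequences."""
    counts = np.zeros(4)
    for seq in sequences:
        idx = _encode(seq)
        counts += np.bincount(idx[idx >= 0], minlength=4)
    if counts.sum() == 0:
        return np.full(4, 0.25)
    return counts / counts.sum()


# ---------------------------------------------------------------------------
# DNA shape


def shape_means(
    seq: str, table: Mapping[str, Sequence[float]]
) -> dict[str, float] | None:
    """Mean pentamer-table value per shape over all valid pentamer windows.

    Pentamers absent from the table are looked up via their reverse
    complement; if both are absent a configuration error is raised.
    """
    n = len(seq)
    if n < 5:
        return None
    seq = seq.upper()
    sums = np.zeros(4)
    count = 0
    for i in range(n - 4):
        penta = seq[i : i + 5]
        if any(b not in _ENCODE for b in penta):
            continue
        values = table.get(penta)
        if values is None:
            values = table.get(reverse_complement(penta))
        if values is None:
            raise ValueError(f"pentamer {penta} (and its reverse complement) missing from shape table")
        sums += np.asarray(values, dtype=float)
        count += 1
    if count == 0:
        return None
    means = sums / count
    return dict(zip(SHAPE_NAMES, means))


def read_shape_table(path) -> dict[str, np.ndarray]:
    """Pentamer shape table TSV: columns pentamer, MGW, HelT, ProT, Roll."""
    df = pd.read_csv(path, sep="\t")
    cols = ["MGW", "HelT", "ProT", "Roll"]
    return {row.iloc[0]: row[cols].to_numpy(dtype=float) for _, row in df.iterrows()}


# ---------------------------------------------------------------------------
# matrix assembly


@dataclass
class FeatureConfig:
    """Which feature families to compute for which regions.

    The default is the full composition model: 4 nucleotide + 16
    dinucleotide percentages in all eight regions (160 variables).
    """

    regions: tuple[str, ...] = REGION_KINDS
    nucleotides: bool = True
    dinucleotides: bool = True
    trinucleotide_regions: tuple[str, ...] = ()
    motif_regions: tuple[str, ...] = ()
    motif_statistic: Literal["max", "sum"] = "max"
    shape_regions: tuple[str, ...] = ()
    double_strand: bool = False
    scan_both_strands: bool = False
    prior: Literal["scanned", "uniform"] = "scanned"

    def __post_init__(self) -> None:
        for region in (
            *self.regions,
            *self.trinucleotide_regions,
            *self.motif_regions,
            *self.shape_regions,
        ):
            if region not in REGION_KINDS:
                raise ValueError(f"unknown region kind {region!r}")


def build_feature_matrix(
    catalog: RegionCatalog,
    config: FeatureConfig | None = None,
    pwms: Sequence[PWM] | None = None,
    shape_table: Mapping[str, Sequence[float]] | None = None,
) -> pd.DataFrame:
    """Assemble the genes x variables matrix for the configured families."""
    config = config or FeatureConfig()
    if config.motif_regions and not pwms:
        raise ValueError("motif features requested but no PWMs provided")
    if config.shape_regions and shape_table is None:
        raise ValueError("shape features requested but no pentamer table provided")

    gene_ids = list(catalog.entries.keys())
    columns: dict[str, dict[str, float]] = {}

    def put(col: str, gid: str, value: float) -> None:
        columns.setdefault(col, {})[gid] = value

    for region in config.regions:
        for gid in gene_ids:
            seq = catalog.entries[gid].regions[region][1]
            if config.nucleotides:
                vals = nt_percentage(seq) if seq else None
                for n in NUCLEOTIDES:
                    put(f"{n}_{region}", gid, np.nan if vals is None else vals[n])
            if config.dinucleotides:
                vals = kmer_percentage(seq, 2) if seq else None
                for d in DINUCLEOTIDES:
                    lab = kmer_label(d)
                    put(f"{lab}_{region}", gid, np.nan if vals is None else vals[lab])
            if region in config.trinucleotide_regions:
                vals = kmer_percentage(seq, 3) if seq else None
                for t in ("".join(p) for p in itertools.product(NUCLEOTIDES, repeat=3)):
                    put(f"{t}_{region}", gid, np.nan if vals is None else vals[t])

    for region in config.motif_regions:
        seqs = catalog.sequences(region)
        if config.prior == "scanned":
            prior = scanned_prior(seqs.values())
        else:
            prior = np.full(4, 0.25)
        score = pwm_score_max if config.motif_statistic == "max" else pwm_score_sum
        for pwm in pwms or ():
            pwm_p = pwm.with_prior(prior)
            col = f"motif:{pwm.motif_id}_{region}"
            for gid, seq in seqs.items():
                value = score(pwm_p, seq, config.scan_both_strands) if seq else np.nan
                put(col, gid, value)

    for region in config.shape_regions:
        for gid in gene_ids:
            seq = catalog.entries[gid].regions[region][1]
            vals = shape_means(seq, shape_table) if seq else None
            for name in SHAPE_NAMES:
                put(f"shape:{name}_{region}", gid, np.nan if vals is None else vals[name])

    matrix = pd.DataFrame(columns, index=pd.Index(gene_ids, name="gene_id"))
    if config.double_strand:
        composition_cols = [
            c
            for c in matrix.columns
            if not c.startswith(("motif:", "shape:")) and "_" in c
        ]
        collapsed = collapse_double_strand(matrix[composition_cols])
        rest = matrix.drop(columns=composition_cols)
        matrix = pd.concat([collapsed, rest], axis=1)
    return matrix


def drop_incomplete_genes(matrix: pd.DataFrame) -> pd.DataFrame:
    """Drop genes with any missing configured feature (logged count)."""
    complete = matrix.dropna(axis=0, how="any")
    dropped = len(matrix) - len(complete)
    if dropped:
        logger.info("dropped %d of %d genes with missing features", dropped, len(matrix))
    return complete
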