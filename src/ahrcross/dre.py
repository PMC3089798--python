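"""Dioxin response element (DRE) scanning, PWM scoring, and conservation.

The AhR:ARNT dimer binds DREs built on the substitution-intolerant 5-bp core
5'-GCGTG-3'.  Promoter windows (default -10 kb .. +1 kb around the TSS) are
scanned for the core on both strands; every hit is extended by 7 bp on each
side to a 19-mer (minus-strand hits are reverse-complemented into DRE
orientation) and scored against a position weight matrix with the
information-weighted matrix-similarity statistic

    MS = (S - S_min) / (S_max - S_min),   S = sum_i c_i * p_i(base_i),

where p_i are pseudocount-smoothed column probabilities and
c_i = 2 + sum_b p_i(b) log2 p_i(b) is the column information weight, so the
consensus scores exactly 1 and the per-position-worst sequence exactly 0.

Cross-species DRE conservation treats each 19-mer as a one-hot vector over
{A,C,G,T} x 19, giving Euclidean distance sqrt(2 * mismatches); complete-
linkage clustering cut at distance 3.0 therefore groups sequences within 4
mismatches of each other, and a multi-species cluster is an "orthologous
DRE".  Core positions are reported as signed TSS-relative offsets of the
core's center base (TSS = 0, upstream negative).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from math import sqrt
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .io import FormatError, PromoterRecord
from .simulate import revcomp

BASES = "ACGT"
BASE_INDEX = {b: i for i, b in enumerate(BASES)}
CORE = "GCGTG"
CORE_LEN = 5
FLANK = 7
SEQ19 = CORE_LEN + 2 * FLANK


# ---------------------------------------------------------------------------
# Core scanning
# ---------------------------------------------------------------------------


@dataclass
class CoreHit:
    """One occurrence of the DRE core in a promoter window."""

    species: str
    gene_id: str
    core_center: int  # TSS-relative position of the core's 3rd base
    strand: str
    core_seq: str
    seq_start: int  # 0-based index of the core's first base in the sequence


@dataclass
class DreHit:
    """A core hit extended to its 19-mer and (optionally) PWM-scored."""

    species: str
    gene_id: str
    core_center: int
    strand: str
    seq19: str
    ms: float | None = None
    chrom: str | None = None
    genome_start: int | None = None


def scan_cores(record: PromoterRecord, core: str = CORE) -> list[CoreHit]:
    """Find every core occurrence on both strands within the TSS window.

    Plus-strand hits match ``core`` directly; minus-strand hits are
    occurrences of its reverse complement (CACGC for GCGTG).  The core
    center is the 0-based start + 2, reported TSS-relative; hits whose
    center falls outside [-upstream_bp, +downstream_bp] are excluded.
    'N' bases never match.
    """
    seq = record.sequence
    hits: list[CoreHit] = []
    for pattern, strand in ((core, "+"), (revcomp(core), "-")):
        j = seq.find(pattern)
        while j != -1:
            center = j + 2 - record.tss_index
            if -record.upstream_bp <= center <= record.downstream_bp:
                hits.append(
                    CoreHit(
                        species=record.species,
                        gene_id=record.gene_id,
                        core_center=center,
                        strand=strand,
                        core_seq=core,
                        seq_start=j,
                    )
                )
            j = seq.find(pattern, j + 1)
    hits.sort(key=lambda h: (h.core_center, h.strand))
    return hits


def extend_to_19mer(hit: CoreHit, record: PromoterRecord) -> DreHit | None:
    """Extend a core hit by 7 bp of flank on each side into DRE orientation.

    Minus-strand hits are reverse-complemented so the reported 19-mer reads
    GCGTG at positions 7..11.  Hits with fewer than 7 bp of flank available
    in the sequence are dropped with a warning (padding would fabricate
    sequence).
    """
    if record.species != hit.species or record.gene_id != hit.gene_id:
        raise ValueError("core hit does not belong to this promoter record")
    start = hit.seq_start - FLANK
    end = hit.seq_start + CORE_LEN + FLANK
    if start < 0 or end > len(record.sequence):
        warnings.warn(
            f"{hit.species}|{hit.gene_id}: core at {hit.core_center:+d} has "
            "insufficient flank for a 19-mer; dropped",
            stacklevel=2,
        )
        return None
    seq19 = record.sequence[start:end]
    if hit.strand == "-":
        seq19 = revcomp(seq19)
    return DreHit(
        species=hit.species,
        gene_id=hit.gene_id,
        core_center=hit.core_center,
        strand=hit.strand,
        seq19=seq19,
    )


def scan_promoter(
    record: PromoterRecord,
    pwm: "Pwm | None" = None,
    core: str = CORE,
    ms_min: float = 0.0,
    strand: str = "both",
) -> list[DreHit]:
    """Scan, extend and (if a PWM is given) score one promoter.

    ``strand='plus'`` restricts to plus-strand core matches for strict
    single-strand reproduction runs.  19-mers containing N are unscoreable
    and dropped when a PWM is supplied.
    """
    hits = []
    for ch in scan_cores(record, core=core):
        if strand == "plus" and ch.strand == "-":
            continue
        dh = extend_to_19mer(ch, record)
        if dh is None:
            continue
        if pwm is not None:
            if any(b not in BASE_INDEX for b in dh.seq19):
                continue
            dh.ms = matrix_similarity(dh.seq19, pwm)
            if dh.ms < ms_min:
                continue
        hits.append(dh)
    return hits


# ---------------------------------------------------------------------------
# Position weight matrix
# ---------------------------------------------------------------------------


@dataclass
class Pwm:
    """19-position PWM with information weights and score normalization."""

    probs: np.ndarray  # (4, 19) column-stochastic
    weights: np.ndarray = field(init=False)  # information content per column
    s_min: float = field(init=False)
    s_max: float = field(init=False)

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        if probs.shape != (4, SEQ19):
            raise FormatError(f"PWM must be 4 x {SEQ19}")
        if not np.allclose(probs.sum(axis=0), 1.0, atol=1e-9):
            raise FormatError("PWM columns must sum to 1")
        self.probs = probs
        with np.errstate(divide="ignore", invalid="ignore"):
            plogp = np.where(probs > 0, probs * np.log2(probs), 0.0)
        self.weights = 2.0 + plogp.sum(axis=0)
        weighted = self.weights * probs
        self.s_min = float(weighted.min(axis=0).sum())
        self.s_max = float(weighted.max(axis=0).sum())
        if not self.s_min < self.s_max:
            raise FormatError("degenerate PWM: s_min == s_max (uniform matrix)")

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.probs.argmax(axis=0))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.probs, index=list(BASES))
        df.loc["weight"] = self.weights
        return df

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def build_pwm(training_seqs: Sequence[str], pseudocount: float = 0.25) -> Pwm:
    """Estimate a PWM from aligned 19-mers with a per-base pseudocount.

    Column probabilities are (count_b + pseudocount) / (n + 4 * pseudocount),
    so n identical sequences give the modal base (n + 0.25) / (n + 1) at the
    default pseudocount.
    """
    seqs = list(training_seqs)
    if len(seqs) < 2:
        raise FormatError("PWM training needs >= 2 sequences")
    for s in seqs:
        if len(s) != SEQ19:
            raise FormatError(f"training sequence of length {len(s)}; need {SEQ19}")
        bad = set(s) - set(BASES)
        if bad:
            raise FormatError(f"training sequence has invalid bases {sorted(bad)}")
    counts = np.zeros((4, SEQ19))
    for s in seqs:
        for i, b in enumerate(s):
            counts[BASE_INDEX[b], i] += 1
    probs = (counts + pseudocount) / (len(seqs) + 4 * pseudocount)
    return Pwm(probs)


def matrix_similarity(seq19: str, pwm: Pwm) -> float:
    """Information-weighted similarity of a 19-mer to the PWM, in [0, 1]."""
    if len(seq19) != SEQ19:
        raise FormatError(f"need a {SEQ19}-mer, got length {len(seq19)}")
    try:
        idx = [BASE_INDEX[b] for b in seq19]
    except KeyError as exc:
        raise FormatError(f"invalid base {exc.args[0]!r} in 19-mer") from exc
    s = float((pwm.weights * pwm.probs[idx, np.arange(SEQ19)]).sum())
    return (s - pwm.s_min) / (pwm.s_max - pwm.s_min)


# ---------------------------------------------------------------------------
# Sequence distance and orthologous-DRE clustering
# ---------------------------------------------------------------------------


def dre_distance(seq_a: str, seq_b: str) -> float:
    """Euclidean distance between one-hot encodings: sqrt(2 * mismatches)."""
    if len(seq_a) != len(seq_b):
        raise FormatError("sequences must have equal length")
    mism = sum(1 for x, y in zip(seq_a, seq_b) if x != y)
    return sqrt(2.0 * mism)


@dataclass
class DreCluster:
    """A cluster of DRE 19-mers, possibly spanning species."""

    members: list[DreHit]
    max_distance: float
    orthologous: bool

    @property
    def species(self) -> set[str]:
        return {h.species for h in self.members}


def cluster_orthologous_dres(
    hits: Iterable[DreHit], theta: float = 3.0
) -> list[DreCluster]:
    """Complete-linkage clustering of DRE 19-mers cut at distance ``theta``.

    Complete linkage guarantees every within-cluster pairwise distance is
    <= theta.  A cluster containing >= 2 species is flagged orthologous.
    Input is sorted by (species, core position, strand) before linkage so
    results are permutation-invariant; pass the hits of one ortholog group.
    """
    hits = sorted(hits, key=lambda h: (h.species, h.core_center, h.strand))
    if not hits:
        return []
    if len(hits) == 1:
        return [DreCluster([hits[0]], 0.0, False)]
    from scipy.cluster.hierarchy import fcluster, linkage
    from scipy.spatial.distance import squareform

    n = len(hits)
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            dist[i, j] = dist[j, i] = dre_distance(hits[i].seq19, hits[j].seq19)
    link = linkage(squareform(dist, checks=False), method="complete")
    labels = fcluster(link, t=theta, criterion="distance")
    clusters: list[DreCluster] = []
    for lab in sorted(set(labels)):
        members = [h for h, l in zip(hits, labels) if l == lab]
        idx = [i for i, l in enumerate(labels) if l == lab]
        max_d = max(
            (dist[i, j] for i in idx for j in idx if i < j), default=0.0
        )
        clusters.append(
            DreCluster(
                members=members,
                max_distance=float(max_d),
                orthologous=len({h.species for h in members}) >= 2,
            )
        )
    return clusters


def positional_conservation(cluster: DreCluster) -> tuple[pd.DataFrame, int]:
    """Signed TSS-relative positions of the cluster members and their spread.

    Descriptive only: no positional threshold is applied.  Spread is
    max(position) - min(position); a single member has spread 0.
    """
    table = pd.DataFrame(
        [
            dict(
                species=h.species,
                gene_id=h.gene_id,
                core_center=h.core_center,
                strand=h.strand,
                seq19=h.seq19,
            )
            for h in cluster.members
        ]
    )
    spread = int(table["core_center"].max() - table["core_center"].min())
    return table, spread
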