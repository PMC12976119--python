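"""Alignment handling and classical mitochondrial-barcode summary statistics.

Works on equal-length haplotype alignments (the study system is a 658-bp
COI barcode fragment).  Columns containing an ambiguous base (N) or a gap
in any sequence are excluded from scoring by default (complete deletion);
a pairwise-deletion mode is available for computing pairwise differences
over pairwise-complete positions instead.

Statistics
----------
S      number of segregating (polymorphic) scored columns
pi     nucleotide diversity: mean number of pairwise differences,
       sum over unordered pairs of Hamming distances / C(n, 2)
D      Tajima's D, the normalised difference between pi and S/a1
Fs     Fu's Fs, ln(S'/(1-S')) with S' = Pr(K >= k_obs) under the Ewens
       sampling formula at theta = pi-hat

Significance for D and Fs is obtained by simulating constant-size
coalescent samples (conditional on a theta estimate from the data:
Watterson's for D, pi-hat for Fs) and counting replicates at least as
extreme as the observation — the standard simulation-based null for
these tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import log
from typing import Iterable, Mapping

import numpy as np
from Bio import SeqIO
from scipy.special import logsumexp

VALID_CHARS = set(b"ACGTN-")
_MISSING = frozenset(b"N-")


class AlignmentError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Containers


class HaplotypeAlignment:
    """Equal-length sequences with a sample -> site mapping.

    Sequences are stored upper-cased as a byte matrix of shape (n, L).
    ``site_ids`` may be None when no spatial mapping exists (pure
    simulation output before placement).
    """

    def __init__(self, sample_ids: list, sequences: Iterable[str] | np.ndarray,
                 site_ids: list | None = None):
        if isinstance(sequences, np.ndarray):
            mat = sequences
        else:
            seqs = [s.upper().encode() if isinstance(s, str) else s.upper()
                    for s in sequences]
            lengths = {len(s) for s in seqs}
            if len(lengths) > 1:
                offenders = [sid for sid, s in zip(sample_ids, seqs)
                             if len(s) != len(seqs[0])]
                raise AlignmentError(
                    f"ragged alignment: sequence lengths differ for {offenders}"
                )
            mat = np.frombuffer(b"".join(seqs), dtype="S1").reshape(len(seqs), -1)
        if len(sample_ids) != mat.shape[0]:
            raise AlignmentError("sample id count does not match sequence count")
        if len(set(sample_ids)) != len(sample_ids):
            raise AlignmentError("duplicate sample ids")
        bad = set(np.unique(mat).tobytes()) - VALID_CHARS
        if bad:
            raise AlignmentError(f"invalid characters in alignment: {bad}")
        if site_ids is not None and len(site_ids) != len(sample_ids):
            raise AlignmentError("site_ids length does not match samples")
        self.sample_ids = list(sample_ids)
        self.site_ids = list(site_ids) if site_ids is not None else None
        self.matrix = mat

    @property
    def n(self) -> int:
        return self.matrix.shape[0]

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    def scored_columns(self) -> np.ndarray:
        """Boolean mask of columns free of N/gap in every sequence."""
        missing = np.isin(self.matrix, [b"N", b"-"])
        return ~missing.any(axis=0)

    def scored_matrix(self) -> np.ndarray:
        return self.matrix[:, self.scored_columns()]

    def subset(self, indices: Iterable[int]) -> "HaplotypeAlignment":
        idx = list(indices)
        return HaplotypeAlignment(
            [self.sample_ids[i] for i in idx],
            self.matrix[idx],
            [self.site_ids[i] for i in idx] if self.site_ids is not None else None,
        )

    def sequences(self) -> list:
        return [row.tobytes().decode() for row in self.matrix]


@dataclass
class HaplotypeTable:
    """Collapsed haplotypes with counts and sites of occurrence."""

    sequences: list                     # representative sequence per haplotype
    counts: list                        # individuals per haplotype
    sites: list                         # set of site ids per haplotype
    members: list                       # sample ids per haplotype
    group: list | None = None

    @property
    def k(self) -> int:
        return len(self.sequences)

    @property
    def n(self) -> int:
        return int(sum(self.counts))


@dataclass
class NeutralityStats:
    n: int
    S: int
    pi: float
    k: int
    tajimas_d: float | None
    p_d_low: float | None
    p_d_high: float | None
    fus_fs: float
    p_fs: float | None
    replicates: int
    flags: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# I/O


def read_alignment(fasta_path, site_map: Mapping | None = None) -> HaplotypeAlignment:
    """Read a FASTA alignment; optionally attach a sample -> site mapping.

    ``site_map`` maps sample id to site id; every sample in the FASTA must
    be present when a map is given.
    """
    records = list(SeqIO.parse(str(fasta_path), "fasta"))
    if not records:
        raise AlignmentError(f"no records in {fasta_path}")
    ids = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    site_ids = None
    if site_map is not None:
        missing = [i for i in ids if i not in site_map]
        if missing:
            raise AlignmentError(f"samples absent from site map: {missing}")
        site_ids = [site_map[i] for i in ids]
    return HaplotypeAlignment(ids, seqs, site_ids)


def write_alignment(alignment: HaplotypeAlignment, path) -> None:
    with open(path, "w") as fh:
        for sid, seq in zip(alignment.sample_ids, alignment.sequences()):
            fh.write(f">{sid}\n{seq}\n")


# ---------------------------------------------------------------------------
# Haplotype collapsing


def collapse_haplotypes(alignment: HaplotypeAlignment) -> HaplotypeTable:
    """Collapse identical sequences (at scored positions) into haplotypes.

    Ordering is deterministic: by count descending, then by sequence.
    """
    scored = alignment.scored_matrix()
    keys: dict = {}
    for i in range(alignment.n):
        keys.setdefault(scored[i].tobytes(), []).append(i)
    items = sorted(keys.items(), key=lambda kv: (-len(kv[1]), kv[0]))
    sequences, counts, sites, members = [], [], [], []
    for _, idx in items:
        sequences.append(alignment.matrix[idx[0]].tobytes().decode())
        counts.append(len(idx))
        members.append([alignment.sample_ids[i] for i in idx])
        if alignment.site_ids is not None:
            sites.append(sorted({alignment.site_ids[i] for i in idx}, key=str))
        else:
            sites.append([])
    return HaplotypeTable(sequences, counts, sites, members)


# ---------------------------------------------------------------------------
# Pairwise differences


def _pairwise_diffs(alignment: HaplotypeAlignment,
                    pairwise_deletion: bool = False) -> np.ndarray:
    """Condensed vector of pairwise Hamming differences (scored positions)."""
    n = alignment.n
    if n < 2:
        raise AlignmentError("need at least two sequences")
    if pairwise_deletion:
        mat = alignment.matrix
        missing = np.isin(mat, [b"N", b"-"])
        out = []
        for i in range(n):
            for j in range(i + 1, n):
                ok = ~(missing[i] | missing[j])
                out.append(int((mat[i, ok] != mat[j, ok]).sum()))
        return np.asarray(out, dtype=int)
    # complete deletion: distances need only be computed between distinct
    # haplotype classes, then expanded by class sizes
    mat = alignment.scored_matrix()
    classes: dict = {}
    for i in range(n):
        classes.setdefault(mat[i].tobytes(), []).append(i)
    reps = np.stack([mat[idx[0]] for idx in classes.values()])
    sizes = np.array([len(idx) for idx in classes.values()])
    k = len(sizes)
    diffs = []
    for i in range(k):
        d_row = (reps[i + 1:] != reps[i]).sum(axis=1) if i + 1 < k else []
        for j, d in enumerate(d_row, start=i + 1):
            diffs.extend([int(d)] * int(sizes[i] * sizes[j]))
    diffs.extend([0] * int((sizes * (sizes - 1) // 2).sum()))
    return np.asarray(diffs, dtype=int)


def mismatch_distribution(alignment: HaplotypeAlignment,
                          pairwise_deletion: bool = False) -> np.ndarray:
    """Counts of pairwise differences, indexed 0..d_max (sums to C(n, 2))."""
    diffs = _pairwise_diffs(alignment, pairwise_deletion)
    return np.bincount(diffs)


def nucleotide_diversity(alignment: HaplotypeAlignment,
                         pairwise_deletion: bool = False) -> float:
    """Mean number of pairwise differences (Nei's pi, per-sample-pair)."""
    return float(_pairwise_diffs(alignment, pairwise_deletion).mean())


def segregating_sites(alignment: HaplotypeAlignment) -> int:
    mat = alignment.scored_matrix()
    return int((mat != mat[0]).any(axis=0).sum())


# ---------------------------------------------------------------------------
# Tajima's D


def _tajima_constants(n: int) -> dict:
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return {"a1": a1, "a2": a2, "e1": e1, "e2": e2}


def tajimas_d_stat(n: int, S: int, pi: float) -> float | None:
    """Tajima's D from summary values; None when S == 0 (undefined)."""
    if n < 4:
        raise AlignmentError("Tajima's D requires n >= 4")
    if S == 0:
        return None
    c = _tajima_constants(n)
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return float((pi - S / c["a1"]) / np.sqrt(var))


def tajimas_d(alignment: HaplotypeAlignment, reps: int = 1000,
              seed: int | None = None) -> tuple[float | None, float | None, float | None]:
    """Tajima's D with simulated-null p-values.

    The null is a constant-size coalescent at Watterson's theta estimated
    from the observed S.  Returns (D, p_lower, p_upper); all None when S=0.
    p_lower is the fraction of replicates with D <= observed (the relevant
    tail for expansion signals), p_upper the analogous upper tail.
    """
    from . import synthetic_data  # local import: avoids a module cycle

    n = alignment.n
    S = segregating_sites(alignment)
    d_obs = tajimas_d_stat(n, S, nucleotide_diversity(alignment))
    if d_obs is None:
        return None, None, None
    c = _tajima_constants(n)
    theta_w = S / c["a1"]
    rng = np.random.default_rng(seed)
    lo = hi = 0
    used = 0
    for _ in range(reps):
        s_rep, pi_rep, _ = synthetic_data.simulate_neutral_summaries(n, theta_w, rng)
        d_rep = tajimas_d_stat(n, s_rep, pi_rep)
        if d_rep is None:
            continue
        used += 1
        if d_rep <= d_obs:
            lo += 1
        if d_rep >= d_obs:
            hi += 1
    if used == 0:
        return d_obs, None, None
    return d_obs, lo / used, hi / used


# ---------------------------------------------------------------------------
# Fu's Fs


def _log_stirling_row(n: int) -> np.ndarray:
    """log unsigned Stirling numbers of the first kind |s(n, k)|, k=0..n."""
    row = np.full(n + 1, -np.inf)
    row[0] = 0.0  # |s(0,0)| = 1
    for m in range(1, n + 1):
        new = np.full(n + 1, -np.inf)
        # |s(m,k)| = |s(m-1,k-1)| + (m-1)|s(m-1,k)|
        new[1:m + 1] = row[0:m]
        if m > 1:
            with np.errstate(invalid="ignore"):
                new[1:m] = np.logaddexp(new[1:m], np.log(m - 1) + row[1:m])
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log Pr(K = k | theta, n) under the Ewens sampling formula, k=0..n."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    ls = _log_stirling_row(n)
    log_rising = np.sum(np.log(theta + np.arange(n)))
    k = np.arange(n + 1)
    return ls + k * log(theta) - log_rising


def fus_fs_stat(n: int, theta_pi: float, k_obs: int) -> tuple[float, list]:
    """Fu's Fs = ln(S'/(1-S')), S' = Pr(K >= k_obs | theta_pi).

    Returns (Fs, flags); boundary cases yield signed infinity with a flag,
    never NaN.
    """
    flags: list = []
    if k_obs <= 1 or theta_pi <= 0:
        # all sequences identical: S' = 1, Fs at the +inf boundary
        flags.append("S' at boundary 1 (monomorphic sample)")
        return float("inf"), flags
    logp = ewens_log_pmf(n, theta_pi)
    log_sp = logsumexp(logp[k_obs:])
    log_1msp = logsumexp(logp[:k_obs])
    if not np.isfinite(log_1msp):
        flags.append("S' at boundary 1")
        return float("inf"), flags
    if not np.isfinite(log_sp):
        flags.append("S' at boundary 0")
        return float("-inf"), flags
    return float(log_sp - log_1msp), flags


def fus_fs(alignment: HaplotypeAlignment, reps: int = 1000,
           seed: int | None = None) -> tuple[float, float | None, list]:
    """Fu's Fs with a simulated neutral null conditional on pi-hat.

    Returns (Fs, p, flags); p = fraction of constant-size coalescent
    replicates (theta = observed pi-hat) with Fs <= observed.
    """
    from . import synthetic_data

    n = alignment.n
    if n < 3:
        raise AlignmentError("Fu's Fs requires n >= 3")
    pi_hat = nucleotide_diversity(alignment)
    k_obs = collapse_haplotypes(alignment).k
    fs_obs, flags = fus_fs_stat(n, pi_hat, k_obs)
    if not np.isfinite(fs_obs):
        return fs_obs, None, flags
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(reps):
        _, pi_rep, k_rep = synthetic_data.simulate_neutral_summaries(n, pi_hat, rng)
        fs_rep, _ = fus_fs_stat(n, pi_rep, k_rep)
        if fs_rep <= fs_obs:
            count += 1
    # never report a literal zero from a finite simulation: use the
    # (k+1)/(B+1) upper bound when no replicate is as extreme
    p = count / reps if count > 0 else 1.0 / (reps + 1)
    return fs_obs, p, flags


# ---------------------------------------------------------------------------
# One-stop summary


def neutrality_stats(alignment: HaplotypeAlignment, reps: int = 1000,
                     seed: int | None = None) -> NeutralityStats:
    """n, S, pi, k, Tajima's D and Fu's Fs with simulation p-values."""
    rng = np.random.default_rng(seed)
    d, p_lo, p_hi = tajimas_d(alignment, reps=reps,
                              seed=int(rng.integers(2 ** 31)))
    fs, p_fs, flags = fus_fs(alignment, reps=reps,
                             seed=int(rng.integers(2 ** 31)))
    return NeutralityStats(
        n=alignment.n,
        S=segregating_sites(alignment),
        pi=nucleotide_diversity(alignment),
        k=collapse_haplotypes(alignment).k,
        tajimas_d=d,
        p_d_low=p_lo,
        p_d_high=p_hi,
        fus_fs=fs,
        p_fs=p_fs,
        replicates=reps,
        flags=flags,
    )
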