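"""Diversity summaries and neutrality tests.

Implements the classic summaries of within-population mtDNA variation —
segregating sites S, mean pairwise differences k̄, nucleotide diversity π —
and the two neutrality statistics most sensitive to demographic growth:

* Tajima's D contrasts k̄ with the Watterson estimator S/a1; an excess of
  rare variants after an expansion drives D negative.
* Fu's Fs is based on the probability, under the Ewens sampling
  distribution with θ set to k̄, of observing at least as many distinct
  haplotypes as were sampled; recent growth inflates the haplotype count
  and makes Fs strongly negative.

Significance is assessed by coalescent simulation (constant population
size), either with θ fixed at the observed k̄ or conditional on the
observed number of segregating sites.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy.special import gammaln, logsumexp

from .seq_io import Alignment, HaplotypeTable, collapse_haplotypes

__all__ = [
    "DiversitySummary",
    "NeutralitySummary",
    "StatisticUndefinedError",
    "diversity",
    "diversity_from_matrix",
    "tajimas_d",
    "ewens_log_pmf",
    "fus_fs",
    "neutrality_pvalues",
]


class StatisticUndefinedError(ValueError):
    """A statistic has no defined value for the given input (e.g. S = 0)."""


@dataclass(frozen=True)
class DiversitySummary:
    """Basic within-sample diversity numbers.

    Attributes
    ----------
    n : sample size
    S : number of segregating sites (over unambiguous residues)
    k_bar : mean number of pairwise nucleotide differences per sequence pair
    pi : nucleotide diversity per site (k_bar / mean usable sites per pair)
    """

    n: int
    S: int
    k_bar: float
    pi: float


@dataclass(frozen=True)
class NeutralitySummary:
    """Neutrality statistics with simulation p-values (lower tail)."""

    D: float
    p_D: float | None
    Fs: float
    p_Fs: float | None
    reps: int
    null: str = "fixed_theta"
    note: str = ""


def _pairwise_stats(enc: np.ndarray) -> tuple[float, float]:
    """Mean pairwise differences and mean usable sites, pairwise deletion.

    ``enc`` is the (n, k) integer-coded matrix from Alignment.encoded().
    """
    n = enc.shape[0]
    diffs = 0.0
    usable = 0.0
    npairs = 0
    for i in range(n):
        a = enc[i]
        both = (a >= 0) & (enc[i + 1 :] >= 0)
        d = ((a != enc[i + 1 :]) & both).sum(axis=1)
        diffs += d.sum()
        usable += both.sum(axis=1).sum()
        npairs += n - 1 - i
    return diffs / npairs, usable / npairs


def diversity(aln: Alignment) -> DiversitySummary:
    """Compute S, k̄ and π for an alignment (pairwise deletion)."""
    if aln.n < 2:
        raise StatisticUndefinedError("diversity requires at least 2 sequences")
    enc = aln.encoded()
    # segregating site: >= 2 distinct unambiguous residues in the column
    S = 0
    for j in range(enc.shape[1]):
        col = enc[:, j]
        vals = np.unique(col[col >= 0])
        if len(vals) >= 2:
            S += 1
    k_bar, mean_usable = _pairwise_stats(enc)
    pi = k_bar / mean_usable if mean_usable > 0 else 0.0
    return DiversitySummary(n=aln.n, S=S, k_bar=float(k_bar), pi=float(pi))


def diversity_from_matrix(
    genotypes: np.ndarray, k: int | None = None
) -> DiversitySummary:
    """Diversity summary for a binary infinite-sites genotype matrix (n, S).

    ``k`` is the nominal sequence length used to normalize π; when omitted,
    π is reported per *segregating* site (the matrix carries no invariant
    columns).
    """
    n, S = genotypes.shape
    if n < 2:
        raise StatisticUndefinedError("diversity requires at least 2 sequences")
    if S == 0:
        return DiversitySummary(n=n, S=0, k_bar=0.0, pi=0.0)
    counts = genotypes.sum(axis=0)
    # sum over sites of (# pairs differing at the site) / (# pairs)
    k_bar = float((counts * (n - counts)).sum()) / (n * (n - 1) / 2)
    denom = k if k is not None else S
    return DiversitySummary(n=n, S=int(S), k_bar=k_bar, pi=k_bar / denom)


def tajimas_d(n: int, S: int, k_bar: float) -> float:
    """Tajima's D from (n, S, k̄).

    D = (k̄ − S/a1) / sqrt(e1·S + e2·S·(S−1)) with the standard constant
    cascade a1, a2, b1, b2, c1, c2, e1, e2.  Raises
    :class:`StatisticUndefinedError` when S = 0 (variance is zero).
    """
    if n < 2:
        raise StatisticUndefinedError("Tajima's D requires n >= 2")
    if S <= 0:
        raise StatisticUndefinedError("Tajima's D is undefined for S = 0")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    var = e1 * S + e2 * S * (S - 1)
    if var <= 0:
        raise StatisticUndefinedError("variance of D is non-positive")
    return float((k_bar - S / a1) / math.sqrt(var))


@lru_cache(maxsize=None)
def _log_stirling_row(n: int) -> np.ndarray:
    """log |s(n, k)| for k = 0..n (unsigned Stirling numbers, first kind).

    Built by the recurrence |s(m+1, k)| = m·|s(m, k)| + |s(m, k−1)| carried
    in log space; n up to a few hundred is exact to ~1e-14 relative.
    """
    row = np.full(n + 1, -np.inf)
    row[1] = 0.0  # |s(1,1)| = 1
    for m in range(1, n):
        new = np.full(n + 1, -np.inf)
        logm = math.log(m)
        new[1 : m + 2] = np.logaddexp(logm + row[1 : m + 2], row[0 : m + 1])
        row = new
    return row


def ewens_log_pmf(n: int, theta: float) -> np.ndarray:
    """log P(K = k) for k = 0..n under the Ewens sampling distribution.

    P(K=k) = |s(n,k)| θ^k / (θ (θ+1) ... (θ+n−1)).  Entry 0 is −inf.
    """
    if theta <= 0:
        raise StatisticUndefinedError("Ewens distribution requires theta > 0")
    logs = _log_stirling_row(n).copy()
    k = np.arange(n + 1)
    logdenom = float(np.log(theta + np.arange(n)).sum())
    return logs + k * math.log(theta) - logdenom


def fus_fs(
    n: int, theta_hat: float, k_obs: int, cap: float | None = None
) -> float:
    """Fu's Fs statistic.

    S' = P(K >= k_obs | θ = theta_hat) under the Ewens sampling
    distribution; Fs = ln S' − ln(1 − S'), evaluated in log space.  When S'
    is numerically 0 or 1 the result is ±inf unless ``cap`` is given, in
    which case ±cap is returned instead.
    """
    if not 1 <= k_obs <= n:
        raise ValueError("k_obs must be in 1..n")
    if theta_hat <= 0:
        raise StatisticUndefinedError("Fu's Fs is undefined for theta_hat = 0")
    logp = ewens_log_pmf(n, theta_hat)
    log_tail = logsumexp(logp[k_obs:])  # log S'
    if k_obs == 1:
        fs = math.inf  # K >= 1 always: S' = 1
    else:
        log_head = logsumexp(logp[1:k_obs])  # log (1 - S')
        if log_tail == -math.inf:
            fs = -math.inf
        else:
            fs = float(log_tail - log_head)
    if cap is not None and math.isinf(fs):
        fs = math.copysign(cap, fs)
    return fs


def _count_haplotypes(genotypes: np.ndarray) -> int:
    return len({row.tobytes() for row in np.ascontiguousarray(genotypes)})


def neutrality_pvalues(
    n: int,
    S: int,
    k_bar: float,
    k_obs: int,
    reps: int = 1000,
    seed: int = 0,
    null: str = "fixed_theta",
) -> NeutralitySummary:
    """Observed D and Fs with lower-tail coalescent-simulation p-values.

    The null is a constant-size coalescent with either θ = k̄
    (``fixed_theta``, the default) or exactly S mutations placed on the
    genealogy (``fixed_S``).  p-values use the add-one rule
    p = (1 + #{sim <= obs}) / (1 + reps) so they are never zero.
    Monomorphic simulated replicates contribute D = 0 and Fs = +inf.
    """
    from . import coalsim  # deferred: circular-import guard

    if reps < 100:
        raise ValueError("reps must be >= 100 for a meaningful p-value")
    if S == 0 or k_bar == 0:
        return NeutralitySummary(
            D=math.nan, p_D=None, Fs=math.nan, p_Fs=None, reps=reps, null=null,
            note="degenerate: no variation in sample",
        )
    D_obs = tajimas_d(n, S, k_bar)
    Fs_obs = fus_fs(n, k_bar, k_obs)

    d_le = 0
    fs_le = 0
    for b in range(reps):
        if null == "fixed_theta":
            sim = coalsim.simulate(
                coalsim.DemographyConfig(
                    model="constant", theta0=k_bar, theta1=k_bar, tau=0.0,
                    n=n, seed=_sub_seed(seed, b),
                )
            )
        elif null == "fixed_S":
            sim = coalsim.fixed_s_sample(n=n, S=S, seed=_sub_seed(seed, b))
        else:
            raise ValueError(f"unknown null: {null!r}")
        g = sim.genotypes
        dsum = diversity_from_matrix(g)
        if dsum.S == 0:
            D_b, Fs_b = 0.0, math.inf
        else:
            D_b = tajimas_d(n, dsum.S, dsum.k_bar)
            Fs_b = fus_fs(n, dsum.k_bar, _count_haplotypes(g))
        if D_b <= D_obs:
            d_le += 1
        if Fs_b <= Fs_obs:
            fs_le += 1
    p_D = (1 + d_le) / (1 + reps)
    p_Fs = (1 + fs_le) / (1 + reps)
    return NeutralitySummary(
        D=D_obs, p_D=p_D, Fs=Fs_obs, p_Fs=p_Fs, reps=reps, null=null
    )


def _sub_seed(seed: int, index: int) -> int:
    """Deterministic per-replicate substream seed below 2**31."""
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def summarize_alignment(aln: Alignment) -> tuple[DiversitySummary, int]:
    """(DiversitySummary, k_obs) for an alignment — convenience wrapper."""
    table: HaplotypeTable = collapse_haplotypes(aln)
    return diversity(aln), table.k_obs
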