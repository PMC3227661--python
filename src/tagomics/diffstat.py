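"""Poisson-based differential tag-count statistics.

Tag counts from two sequencing libraries are compared with the exact
conditional Poisson test of Audic & Claverie: given ``x`` tags at a locus in
a library of ``n1`` total tags, the count ``y`` in a second library of ``n2``
tags follows, under the null of equal per-tag rates, the distribution

    p(k | x) = r^k (x+k)! / (x! k! (1+r)^(x+k+1)),   r = n2/n1,

i.e. a negative binomial with x+1 successes and success probability
1/(1+r).  The two-sided p-value doubles the smaller tail and caps at 1.
Significance calls follow FDR <= 0.05 and |log2Ratio| >= 1 on TPM-normalized
abundances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

__all__ = [
    "LibraryPair",
    "DifferentialRecord",
    "normalize_tpm",
    "ac_pvalue",
    "bh_adjust",
    "call_differential",
    "compare_region_distributions",
]


@dataclass(frozen=True)
class LibraryPair:
    """One locus' tag counts in two libraries (tumor x/n1, normal y/n2)."""

    x: int
    y: int
    n1: int
    n2: int

    def __post_init__(self):
        for name in ("x", "y", "n1", "n2"):
            v = getattr(self, name)
            if v != int(v):
                raise ValueError(f"{name} must be an integer tag count, got {v!r}")
        if self.x < 0 or self.y < 0:
            raise ValueError("counts must be non-negative")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("library sizes must be positive")


@dataclass(frozen=True)
class DifferentialRecord:
    locus_id: str
    tpm_tumor: float
    tpm_normal: float
    log2_ratio: float
    p_value: float
    fdr: float
    significant: bool
    direction: str  # "up" | "down" | "none" (sign of the tag log2 ratio)


def normalize_tpm(count, library_size):
    """Tags per million: count / library_size * 1e6 (vectorized)."""
    library_size = np.asarray(library_size, dtype=float)
    if np.any(library_size <= 0):
        raise ValueError("library_size must be positive")
    return np.asarray(count, dtype=float) / library_size * 1e6


def _log_pmf(k: np.ndarray, x: int, log_r: float, log_1pr: float) -> np.ndarray:
    return (
        k * log_r
        + gammaln(x + k + 1)
        - gammaln(x + 1)
        - gammaln(k + 1)
        - (x + k + 1) * log_1pr
    )


def ac_pvalue(pair: LibraryPair, method: str = "doubling") -> float:
    """Exact two-sided p-value for a tag count observed in two libraries.

    ``method="doubling"`` (default): 2 x the smaller of P(K <= y), P(K >= y),
    capped at 1.  ``method="mass"``: sum of all probability masses not
    exceeding the observed one (minimum-likelihood two-sided convention).
    Tail sums are computed in log space; accuracy ~1e-12 versus direct
    summation.

    The conditional construction is applied in a canonical orientation --
    conditioning on the smaller count (ties broken by library size) -- which
    makes the test exchangeable: swapping the two libraries leaves the
    p-value identical.
    """
    x, y, n1, n2 = pair.x, pair.y, pair.n1, pair.n2
    if (y, n2) < (x, n1):
        x, y, n1, n2 = y, x, n2, n1
    r = n2 / n1
    log_r, log_1pr = np.log(r), np.log1p(r)
    k = np.arange(0, y + 1, dtype=np.int64)
    lp = _log_pmf(k.astype(float), x, log_r, log_1pr)
    lower = min(1.0, float(np.exp(logsumexp(lp))))  # P(K <= y)
    pmf_y = float(np.exp(lp[-1]))
    # P(K >= y) by complement; clamp the float cancellation to [pmf_y, 1]
    upper = min(1.0, max(pmf_y, 1.0 - (lower - pmf_y)))
    if method == "doubling":
        return min(1.0, 2.0 * min(lower, upper))
    if method == "mass":
        # enumerate the support out to negligible tail mass and sum the
        # masses <= p(y); the pmf is unimodal so this is the two-tailed set
        masses = [float(np.exp(v)) for v in lp]
        total = sum(masses)
        kk = y + 1
        while total < 1.0 - 1e-15:
            m = float(np.exp(_log_pmf(np.array([float(kk)]), x, log_r, log_1pr)[0]))
            masses.append(m)
            total += m
            if m < 1e-18 and kk > (x + 1) * r:
                break
            kk += 1
        thresh = pmf_y * (1 + 1e-12)
        return min(1.0, sum(m for m in masses if m <= thresh))
    raise ValueError(f"unknown method {method!r}")


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def call_differential(
    locus_ids: Sequence[str],
    x: Sequence[int],
    y: Sequence[int],
    n1: int,
    n2: int,
    lfc_threshold: float = 1.0,
    fdr_threshold: float = 0.05,
    pseudo: float = 0.5,
    method: str = "doubling",
) -> pd.DataFrame:
    """Per-locus differential table from pooled tumor (x/n1) vs normal (y/n2) counts.

    log2_ratio = log2((tpm_tumor + pseudo) / (tpm_normal + pseudo)); the
    pseudocount applies to the ratio only -- p-values use the raw integer
    counts.  ``significant`` iff fdr <= fdr_threshold and |log2_ratio| >=
    lfc_threshold (inclusive, as printed); ``direction`` is the sign of the
    tag ratio.
    """
    x = np.asarray(x, dtype=np.int64)
    y = np.asarray(y, dtype=np.int64)
    tpm_t = normalize_tpm(x, n1)
    tpm_n = normalize_tpm(y, n2)
    log2_ratio = np.log2((tpm_t + pseudo) / (tpm_n + pseudo))
    cache: dict[tuple[int, int], float] = {}
    pvals = np.empty(len(x))
    for i, (xi, yi) in enumerate(zip(x, y)):
        key = (int(xi), int(yi))
        if key not in cache:
            cache[key] = ac_pvalue(LibraryPair(key[0], key[1], n1, n2), method=method)
        pvals[i] = cache[key]
    fdr = bh_adjust(pvals)
    significant = (fdr <= fdr_threshold) & (np.abs(log2_ratio) >= lfc_threshold)
    direction = np.where(log2_ratio > 0, "up", np.where(log2_ratio < 0, "down", "none"))
    return pd.DataFrame(
        {
            "locus_id": list(locus_ids),
            "x": x,
            "y": y,
            "n1": n1,
            "n2": n2,
            "tpm_tumor": tpm_t,
            "tpm_normal": tpm_n,
            "log2_ratio": log2_ratio,
            "p_value": pvals,
            "fdr": fdr,
            "significant": significant,
            "direction": direction,
        }
    )


def compare_region_distributions(
    groups_by_class: Mapping[str, tuple[Sequence[float], Sequence[float]]],
) -> dict[str, float]:
    """Two-sided Wilcoxon rank-sum p-value per genic region class.

    Each class supplies the tumor and normal log2 tag-abundance samples;
    the null is zero distributional shift.  Exact enumeration when both
    groups have <= 12 observations and no ties; otherwise the normal
    approximation with tie correction.  Degenerate all-tied input yields
    p = 1 with a warning.
    """
    out: dict[str, float] = {}
    for cls, (a, b) in groups_by_class.items():
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.size < 2 or b.size < 2:
            raise ValueError(f"class {cls!r} needs at least 2 observations per group")
        combined = np.concatenate([a, b])
        if np.all(combined == combined[0]):
            warnings.warn(f"class {cls!r}: all observations tied; p set to 1")
            out[cls] = 1.0
            continue
        has_ties = len(np.unique(combined)) < combined.size
        method = "exact" if (a.size <= 12 and b.size <= 12 and not has_ties) else "asymptotic"
        res = mannwhitneyu(a, b, alternative="two-sided", method=method)
        out[cls] = float(min(1.0, res.pvalue))
    return out
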