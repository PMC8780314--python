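"""Count normalization, exact two-group testing, BH adjustment, and screening.

The two-group test is a conditional binomial exact test: pooling counts
within each group, the group-A total A given the grand total N = A + B is
Binomial(N, pi) under the null, with pi the group-A share of the summed
library sizes. The two-sided p-value sums the probabilities of all outcomes
no more likely than the observed one ("minlike"). This is the dispersion->0
(Poisson) limit of the negative-binomial exact test used by count-based DE
packages; it is documented as a stand-in, not a clone.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Sequence

import numpy as np
from scipy import stats

from .io_formats import CountMatrix


class Direction(str, Enum):
    UP = "up"
    DOWN = "down"
    NS = "ns"


@dataclass(frozen=True)
class DEParams:
    min_cpm: float = 50.0
    min_abs_log2fc: float = 1.0
    max_fdr: float = 0.05
    pseudocount: float = 0.5
    strict_inequalities: bool = False

    def __post_init__(self) -> None:
        if self.min_abs_log2fc < 0:
            raise ValueError("min_abs_log2fc must be >= 0")
        if not (0 < self.max_fdr <= 1):
            raise ValueError("max_fdr must be in (0, 1]")


@dataclass(frozen=True)
class ContrastResult:
    feature_id: str
    group_a: str
    group_b: str
    mean_cpm_a: float
    mean_cpm_b: float
    log2fc: float
    pvalue: float | None  # None for features excluded by the CPM filter
    fdr: float | None
    direction: Direction

    @property
    def contrast(self) -> tuple[str, str]:
        return (self.group_a, self.group_b)


def cpm(counts: np.ndarray | Sequence[float], library_size: int) -> np.ndarray:
    """Counts per million: count * 1e6 / library_size (no pseudocount)."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    return np.asarray(counts, dtype=float) * 1e6 / library_size


def log2_fold_change(
    mean_cpm_a: float, mean_cpm_b: float, pseudocount: float = 0.5
) -> float:
    """log2((b + pseudocount) / (a + pseudocount)); b over a."""
    if mean_cpm_a < 0 or mean_cpm_b < 0:
        raise ValueError("mean CPM must be >= 0")
    num = mean_cpm_b + pseudocount
    den = mean_cpm_a + pseudocount
    if num == 0 and den == 0:
        return 0.0
    return float(np.log2(num / den))


# Relative tolerance when comparing outcome probabilities to the observed
# one: guards against float noise excluding outcomes of equal likelihood.
_MINLIKE_RELTOL = 1e-7


def exact_count_test(
    counts_a: Sequence[int],
    counts_b: Sequence[int],
    libsizes_a: Sequence[int],
    libsizes_b: Sequence[int],
) -> float:
    """Two-sided conditional binomial exact test on pooled counts."""
    A = int(np.sum(counts_a))
    B = int(np.sum(counts_b))
    N = A + B
    if N == 0:
        return 1.0
    la = float(np.sum(libsizes_a))
    lb = float(np.sum(libsizes_b))
    if la <= 0 or lb <= 0:
        raise ValueError("library sizes must be positive")
    pi = la / (la + lb)
    pmf = stats.binom.pmf(np.arange(N + 1), N, pi)
    p_obs = pmf[A]
    p = float(pmf[pmf <= p_obs * (1.0 + _MINLIKE_RELTOL)].sum())
    # extreme observations can underflow the pmf to exactly 0; keep p in (0,1]
    return min(max(p, 1e-320), 1.0)


def bh_adjust(pvalues: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjustment, input order preserved."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def _passes(value: float, threshold: float, strict: bool, kind: str) -> bool:
    if kind == "ge":
        return value > threshold if strict else value >= threshold
    return value < threshold if strict else value <= threshold


def screen_contrast(
    matrix: CountMatrix,
    group_a: Sequence[str],
    group_b: Sequence[str],
    params: DEParams = DEParams(),
    label_a: str | None = None,
    label_b: str | None = None,
) -> list[ContrastResult]:
    """Per-feature DE screen for one two-group contrast.

    Features must reach ``min_cpm`` in at least one sample of either group to
    be tested; BH is applied across the tested features only. Direction is
    up/down when both the fold-change and FDR thresholds pass (inclusive
    comparisons by default, strict in ``strict_inequalities`` mode).
    """
    ga, gb = list(group_a), list(group_b)
    if not ga or not gb:
        raise ValueError("both groups must be non-empty")
    if set(ga) & set(gb):
        raise ValueError(f"overlapping groups: {sorted(set(ga) & set(gb))}")
    idx_a = [matrix.sample_ids.index(s) for s in ga]
    idx_b = [matrix.sample_ids.index(s) for s in gb]
    label_a = label_a or "+".join(ga)
    label_b = label_b or "+".join(gb)

    lib = matrix.library_sizes.astype(float)
    cpm_all = matrix.counts / lib[None, :] * 1e6
    cpm_a = cpm_all[:, idx_a]
    cpm_b = cpm_all[:, idx_b]
    max_cpm = np.maximum(cpm_a.max(axis=1), cpm_b.max(axis=1))
    tested = np.array(
        [_passes(m, params.min_cpm, params.strict_inequalities, "ge")
         for m in max_cpm]
    )

    pvals: dict[int, float] = {}
    for i in np.nonzero(tested)[0]:
        pvals[int(i)] = exact_count_test(
            matrix.counts[i, idx_a],
            matrix.counts[i, idx_b],
            matrix.library_sizes[idx_a],
            matrix.library_sizes[idx_b],
        )
    tested_idx = sorted(pvals)
    fdrs = bh_adjust([pvals[i] for i in tested_idx]) if tested_idx else np.array([])
    fdr_map = {i: float(q) for i, q in zip(tested_idx, fdrs)}

    results: list[ContrastResult] = []
    for i, fid in enumerate(matrix.feature_ids):
        mean_a = float(cpm_a[i].mean())
        mean_b = float(cpm_b[i].mean())
        lfc = log2_fold_change(mean_a, mean_b, params.pseudocount)
        if i in fdr_map:
            pv, q = pvals[i], fdr_map[i]
            sig = _passes(q, params.max_fdr, params.strict_inequalities, "le")
            big = _passes(abs(lfc), params.min_abs_log2fc,
                          params.strict_inequalities, "ge")
            if sig and big:
                direction = Direction.UP if lfc > 0 else Direction.DOWN
            else:
                direction = Direction.NS
        else:
            pv, q = None, None
            direction = Direction.NS
        results.append(
            ContrastResult(fid, label_a, label_b, mean_a, mean_b, lfc, pv, q,
                           direction)
        )
    return results


def write_contrast_results(results: Sequence[ContrastResult], path) -> None:
    with open(path, "w") as fh:
        fh.write(
            "feature_id\tgroup_a\tgroup_b\tmean_cpm_a\tmean_cpm_b\tlog2fc\t"
            "pvalue\tfdr\tdirection\n"
        )
        for r in results:
            pv = "" if r.pvalue is None else f"{r.pvalue:.6g}"
            q = "" if r.fdr is None else f"{r.fdr:.6g}"
            fh.write(
                f"{r.feature_id}\t{r.group_a}\t{r.group_b}\t{r.mean_cpm_a:.6g}\t"
                f"{r.mean_cpm_b:.6g}\t{r.log2fc:.6g}\t{pv}\t{q}\t{r.direction.value}\n"
            )
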