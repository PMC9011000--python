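"""circRNA abundance (RPM), count-based differential expression, and the
2^-ΔΔCt relative-expression computation.

The differential test is an exact Poisson rate comparison on pooled group
counts: conditional on the total, the group-A count is binomial with the
library-size proportion as success probability, so the two-sided p-value is
an exact binomial tail.  The decision rule is the conventional one for this
kind of screen: linear fold change ≥ 2 and raw p < 0.05, no multiplicity
correction.  An optional negative-binomial variant with a single
method-of-moments common dispersion is provided for overdispersed counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import ExpressionMatrix


class InputError(ValueError):
    pass


def compute_rpm(
    counts: ExpressionMatrix, mapped_totals: pd.Series
) -> ExpressionMatrix:
    """Reads per million mapped reads: count / mapped_total × 10^6."""
    missing = [s for s in counts.samples if s not in mapped_totals.index]
    if missing:
        raise InputError(f"samples without a mapped-read total: {missing}")
    totals = mapped_totals.loc[counts.samples].astype(float)
    if (totals <= 0).any():
        bad = list(totals.index[totals <= 0])
        raise InputError(f"non-positive mapped totals for samples: {bad}")
    rpm = counts.data.div(totals, axis=1) * 1e6
    return ExpressionMatrix(rpm, counts.groups, units="RPM")


@dataclass
class DEResult:
    feature_id: str
    contrast: tuple[str, str]
    log2_fold_change: float
    p_value: float
    direction: str  # up / down (group B relative to group A)
    significant: bool


def _common_dispersion(norm: np.ndarray, group_idx: list[np.ndarray]) -> float:
    """Method-of-moments common NB dispersion across features, using
    within-group means/variances of library-size-normalized counts."""
    phis = []
    for idx in group_idx:
        sub = norm[:, idx]
        if sub.shape[1] < 2:
            continue
        m = sub.mean(axis=1)
        v = sub.var(axis=1, ddof=1)
        ok = m > 0
        if ok.any():
            phis.append(np.median((v[ok] - m[ok]) / m[ok] ** 2))
    if not phis:
        return 0.0
    return float(max(0.0, np.median(phis)))


def _nb_conditional_p(a: int, total: int, mu_a: float, mu_b: float,
                      phi: float) -> float:
    """Two-sided exact tail of A's count conditional on the pooled total,
    under independent NB(mu, phi) group sums (minimum-likelihood rule)."""
    r_a, r_b = 1.0 / phi, 1.0 / phi
    x = np.arange(total + 1)
    logpmf = stats.nbinom.logpmf(x, r_a, r_a / (r_a + mu_a)) + stats.nbinom.logpmf(
        total - x, r_b, r_b / (r_b + mu_b)
    )
    logpmf -= logpmf.max()
    pmf = np.exp(logpmf)
    pmf /= pmf.sum()
    return float(min(1.0, pmf[pmf <= pmf[a] * (1 + 1e-12)].sum()))


def test_de(
    counts: ExpressionMatrix,
    group_a: str,
    group_b: str,
    method: str = "exact-poisson",
    pseudocount: float = 0.5,
    fold_change: float = 2.0,
    alpha: float = 0.05,
    lib_sizes: pd.Series | None = None,
) -> list[DEResult]:
    """Per-feature differential test between two groups.

    ``lib_sizes`` defaults to per-sample column sums.  The fold change is
    computed on library-size-normalized group means with a pseudocount, on
    the linear scale, reported as log2 (B relative to A).
    """
    if method not in ("exact-poisson", "nb-common"):
        raise InputError(f"unknown method {method!r}")
    samples_a = counts.group_samples(group_a)
    samples_b = counts.group_samples(group_b)
    if not samples_a or not samples_b:
        raise InputError(f"empty group in contrast ({group_a}, {group_b})")
    mat = counts.data[samples_a + samples_b].to_numpy()
    if not np.allclose(mat, np.round(mat)):
        raise InputError("exact tests require integer counts")
    mat = np.round(mat).astype(np.int64)

    if lib_sizes is None:
        lib_sizes = counts.data.sum(axis=0)
    libs = lib_sizes.loc[samples_a + samples_b].to_numpy(dtype=float)
    if (libs <= 0).any():
        raise InputError("non-positive library size")
    na = len(samples_a)
    lib_a, lib_b = libs[:na].sum(), libs[na:].sum()

    # normalized (per-million) means for the fold change; computed as a
    # difference of logs so swapping the groups negates it bit-exactly
    norm = mat / libs * 1e6
    mean_a = norm[:, :na].mean(axis=1)
    mean_b = norm[:, na:].mean(axis=1)
    lfc = np.log2(mean_b + pseudocount) - np.log2(mean_a + pseudocount)

    a_sum = mat[:, :na].sum(axis=1)
    b_sum = mat[:, na:].sum(axis=1)

    phi = 0.0
    if method == "nb-common":
        group_idx = [np.arange(na), np.arange(na, mat.shape[1])]
        phi = _common_dispersion(norm, group_idx)

    # evaluate the two-sided tail in a canonical group orientation so that
    # swapping the contrast preserves the p-value bit-exactly
    if group_a <= group_b:
        canon = lambda a, b: (a, lib_a, b, lib_b)  # noqa: E731
    else:
        canon = lambda a, b: (b, lib_b, a, lib_a)  # noqa: E731

    results = []
    for i, feat in enumerate(counts.features):
        a, b = int(a_sum[i]), int(b_sum[i])
        total = a + b
        if total == 0:
            p, l2 = 1.0, 0.0
        elif method == "nb-common" and phi > 0:
            x, lx, _y, ly = canon(a, b)
            pooled = total / (lx + ly)
            p = _nb_conditional_p(x, total, pooled * lx, pooled * ly, phi)
            l2 = float(lfc[i])
        else:
            x, lx, _y, ly = canon(a, b)
            p = stats.binomtest(x, total, lx / (lx + ly)).pvalue
            l2 = float(lfc[i])
        sig = abs(l2) >= np.log2(fold_change) and p < alpha
        results.append(
            DEResult(
                feature_id=feat,
                contrast=(group_a, group_b),
                log2_fold_change=l2,
                p_value=float(p),
                direction="up" if l2 > 0 else "down",
                significant=bool(sig),
            )
        )
    return results


def de_table(results: list[DEResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "feature_id": [r.feature_id for r in results],
            "group_a": [r.contrast[0] for r in results],
            "group_b": [r.contrast[1] for r in results],
            "log2_fold_change": [r.log2_fold_change for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
            "significant": [r.significant for r in results],
        }
    )


def relative_expression(
    ct_target_sample: float,
    ct_ref_sample: float,
    ct_target_calibrator: float,
    ct_ref_calibrator: float,
) -> float:
    """2^-ΔΔCt relative expression from quantification-cycle values."""
    cts = (ct_target_sample, ct_ref_sample, ct_target_calibrator, ct_ref_calibrator)
    if not all(np.isfinite(c) for c in cts):
        raise InputError("Ct values must be finite")
    ddct = (ct_target_sample - ct_ref_sample) - (
        ct_target_calibrator - ct_ref_calibrator
    )
    return float(2.0 ** (-ddct))
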