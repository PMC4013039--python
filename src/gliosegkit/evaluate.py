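"""Agreement metrics between label maps and the study's statistical tests.

Overlap between an automatic and a reference segmentation is summarized per
compound region (CETV, TV, TV+) by the Dice coefficient 2|A&R|/(|A|+|R|),
positive predictive value |A&R|/|A|, sensitivity |A&R|/|R|, and absolute /
signed relative volume errors (positive relative error = oversegmentation).

Conventions for degenerate masks: Dice of two empty masks is 1 (perfect
agreement on absence, needed when a phantom lacks a compartment) and 0 when
exactly one is empty; PPV and sensitivity with an empty denominator are
reported as NaN (missing), never as 0.

The rank statistics mirror a clinical comparison workflow: Wilcoxon signed
rank (exact sign-flip null for small n, normal approximation with tie
correction otherwise), Spearman rank correlation (exact permutation null for
small n), Friedman and Kruskal-Wallis non-parametric ANOVA, and multi-class
Cohen's kappa over the tumor neighborhood.
"""

from __future__ import annotations

import dataclasses
import itertools
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats
from sklearn.metrics import cohen_kappa_score

from .segment import COMPOUND_REGIONS, compound_mask, volume_ml
from .volumes_io import LabelMap

WILCOXON_EXACT_N = 12
SPEARMAN_EXACT_N = 8


@dataclasses.dataclass
class OverlapReport:
    region: str
    dice: float
    ppv: float
    sensitivity: float
    vol_auto_ml: float
    vol_ref_ml: float
    abs_err_ml: float
    rel_err: float


@dataclasses.dataclass
class StatResult:
    test: str
    statistic: float
    p_value: float
    n: int
    notes: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_value <= 1.0 or np.isnan(self.p_value)):
            raise ValueError(f"p-value out of range: {self.p_value}")


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")


def dice(a: np.ndarray, b: np.ndarray) -> float:
    """Dice overlap in [0, 1]; empty-vs-empty -> 1, one-empty -> 0."""
    a = np.asarray(a, dtype=bool)
    b = np.asarray(b, dtype=bool)
    _check_shapes(a, b)
    na, nb = int(a.sum()), int(b.sum())
    if na + nb == 0:
        return 1.0
    return 2.0 * int((a & b).sum()) / (na + nb)


def ppv_sensitivity(auto: np.ndarray, ref: np.ndarray) -> tuple[float, float]:
    """(PPV, sensitivity); an undefined quotient is NaN, not 0."""
    auto = np.asarray(auto, dtype=bool)
    ref = np.asarray(ref, dtype=bool)
    _check_shapes(auto, ref)
    tp = int((auto & ref).sum())
    na, nr = int(auto.sum()), int(ref.sum())
    ppv = tp / na if na > 0 else float("nan")
    sens = tp / nr if nr > 0 else float("nan")
    return ppv, sens


def overlap_report(auto: LabelMap, ref: LabelMap) -> list[OverlapReport]:
    """One row per compound region (CETV, TV, TVPLUS)."""
    if auto.shape != ref.shape or auto.spacing != ref.spacing:
        raise ValueError("label maps must share grid and spacing")
    rows = []
    for region in ("CETV", "TV", "TVPLUS"):
        am = compound_mask(auto, region)
        rm = compound_mask(ref, region)
        ppv, sens = ppv_sensitivity(am, rm)
        va = volume_ml(am, auto.spacing)
        vr = volume_ml(rm, ref.spacing)
        rel = (va - vr) / vr if vr > 0 else float("nan")
        rows.append(OverlapReport(
            region=region, dice=dice(am, rm), ppv=ppv, sensitivity=sens,
            vol_auto_ml=va, vol_ref_ml=vr, abs_err_ml=abs(va - vr), rel_err=rel,
        ))
    return rows


# ---------------------------------------------------------------------------
# rank statistics


def _signed_rank_statistic(d: np.ndarray) -> tuple[float, np.ndarray]:
    ranks = stats.rankdata(np.abs(d))
    w_pos = float(ranks[d > 0].sum())
    return w_pos, ranks


def wilcoxon_signed_rank(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Two-sided paired test on x - y.

    Zero differences are dropped (>= 5 pairs must remain). For n <= 12 the
    exact sign-flip null of the positive-rank sum W+ is enumerated (2^n
    outcomes, ties handled through midranks); otherwise the normal
    approximation with tie correction is used.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("paired samples must have equal length")
    d = x - y
    d = d[d != 0]
    if d.size == 0:
        raise ValueError("all differences zero")
    n = d.size
    if n < 5:
        raise ValueError("need >= 5 nonzero paired differences")
    w_obs, ranks = _signed_rank_statistic(d)
    if n <= WILCOXON_EXACT_N:
        # all 2^n assignments of signs to the midranks
        signs = (
            (np.arange(2 ** n)[:, None] >> np.arange(n)[None, :]) & 1
        ).astype(np.float64)
        w_null = signs @ ranks
        p_le = np.mean(w_null <= w_obs + 1e-12)
        p_ge = np.mean(w_null >= w_obs - 1e-12)
        p = min(1.0, 2.0 * min(p_le, p_ge))
        notes = {"method": "exact sign-flip enumeration", "two_sided": True}
    else:
        res = stats.wilcoxon(
            x, y, zero_method="wilcox", correction=False, method="approx",
            alternative="two-sided",
        )
        p = float(res.pvalue)
        notes = {"method": "normal approximation, tie-corrected", "two_sided": True}
    return StatResult(
        test="wilcoxon_signed_rank", statistic=w_obs, p_value=p, n=n, notes=notes
    )


def spearman_rho(x: Sequence[float], y: Sequence[float]) -> StatResult:
    """Spearman rank correlation (Pearson on midranks).

    Exact permutation p-value (all n! orderings, two-sided on |rho|) for
    n <= 8, t-approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("samples must have equal length")
    n = x.size
    if n < 3:
        raise ValueError("need at least 3 observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise ValueError("constant input vector")
    rho = float(stats.spearmanr(x, y).statistic)
    if n <= SPEARMAN_EXACT_N:
        rx = stats.rankdata(x)
        ry = stats.rankdata(y)
        perms = np.array(list(itertools.permutations(range(n))), dtype=np.intp)
        mat = ry[perms]  # (n!, n) permuted rank vectors
        rxc = rx - rx.mean()
        mc = mat - mat.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc ** 2).sum() * (mc ** 2).sum(axis=1))
        rhos = (mc @ rxc) / denom  # ties in y make all denoms equal, > 0
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
        notes = {"method": "exact permutation", "two_sided": True}
    else:
        p = float(stats.spearmanr(x, y).pvalue)
        notes = {"method": "t approximation", "two_sided": True}
    return StatResult(test="spearman_rho", statistic=rho, p_value=p, n=n, notes=notes)


def friedman(groups: Sequence[Sequence[float]]) -> StatResult:
    """Friedman rank test across k >= 3 paired series (tie-corrected)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    k = len(arrs)
    if k < 3:
        raise ValueError("Friedman test needs k >= 3 paired series")
    lengths = {a.size for a in arrs}
    if len(lengths) != 1:
        raise ValueError("paired series must have equal length")
    n = arrs[0].size
    data = np.column_stack(arrs)
    if np.all(np.ptp(data, axis=1) == 0):
        # every block fully tied: no evidence of any difference
        return StatResult(
            test="friedman", statistic=0.0, p_value=1.0, n=n,
            notes={"k": k, "df": k - 1, "degenerate": "all blocks tied"},
        )
    res = stats.friedmanchisquare(*arrs)
    return StatResult(
        test="friedman", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=n,
        notes={"k": k, "df": k - 1, "approx": "chi-square"},
    )


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> StatResult:
    """Kruskal-Wallis H test across k >= 2 independent groups (tie-corrected)."""
    arrs = [np.asarray(g, dtype=float) for g in groups]
    if len(arrs) < 2:
        raise ValueError("Kruskal-Wallis needs k >= 2 groups")
    if any(a.size == 0 for a in arrs):
        raise ValueError("empty group")
    res = stats.kruskal(*arrs)
    n = int(sum(a.size for a in arrs))
    return StatResult(
        test="kruskal_wallis", statistic=float(res.statistic),
        p_value=float(res.pvalue), n=n,
        notes={"k": len(arrs), "df": len(arrs) - 1, "approx": "chi-square"},
    )


def cohen_kappa(
    auto: LabelMap, ref: LabelMap, support_dilation: int = 1
) -> StatResult:
    """Multi-class kappa over the 5-code confusion matrix.

    The support is the union of both tumor extents dilated by
    ``support_dilation`` voxels (26-connectivity): whole-brain kappa would be
    dominated by background agreement.
    """
    if auto.shape != ref.shape:
        raise ValueError("label maps must share one grid")
    union = (auto.codes > 0) | (ref.codes > 0)
    if not union.any():
        raise ValueError("no tumor voxels in either label map")
    if support_dilation > 0:
        union = ndimage.binary_dilation(
            union, structure=np.ones((3, 3, 3), dtype=bool),
            iterations=support_dilation,
        )
    a = auto.codes[union].astype(int)
    r = ref.codes[union].astype(int)
    po = float(np.mean(a == r))
    marg_a = np.bincount(a, minlength=5) / a.size
    marg_r = np.bincount(r, minlength=5) / r.size
    pe = float(marg_a @ marg_r)
    if pe >= 1.0 - 1e-15:
        raise ValueError("chance agreement pe = 1; kappa undefined")
    kappa = float(cohen_kappa_score(a, r))
    return StatResult(
        test="cohen_kappa", statistic=kappa, p_value=float("nan"), n=int(a.size),
        notes={"po": po, "pe": pe, "support": "tumor union + dilation"},
    )
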