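"""Statistical procedures: paired t maps with FDR control,
repeated-measures ANOVA, behavioral reaction-time analysis, and
hierarchical linear regression.

Multiple-comparison policy: Benjamini–Hochberg step-up FDR for large
frequency × time (× location) families, Bonferroni for small post-hoc
families.  Repeated-measures ANOVAs block on subject and test each
effect against its effect × subject interaction mean square.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "StatMap",
    "HLRResult",
    "paired_t",
    "bh_fdr",
    "bonferroni",
    "paired_t_map",
    "rm_anova",
    "behavior_stats",
    "hlr_compare",
]


def paired_t(a: np.ndarray, b: np.ndarray) -> tuple[float, float, int]:
    """Two-tailed paired Student's t-test; returns (t, p, df).

    Zero-variance differences are guarded: identical samples give
    (0, 1); a constant nonzero difference gives t = ±inf, p = 0.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape or a.ndim != 1 or len(a) < 2:
        raise ValueError("paired_t needs two equal-length 1-D samples, n >= 2")
    d = a - b
    df = len(d) - 1
    sd = d.std(ddof=1)
    if sd == 0.0:
        if d.mean() == 0.0:
            return 0.0, 1.0, df
        return float(np.sign(d.mean()) * np.inf), 0.0, df
    res = sp_stats.ttest_rel(a, b)
    return float(res.statistic), float(res.pvalue), df


def bh_fdr(p_values: np.ndarray, q: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up procedure.

    Rejects all sorted p(i) with i ≤ max{i : p(i) ≤ i·q/m}; adjusted
    p-values use the standard monotone cumulative-minimum transform,
    so ``reject ⇔ p_adjusted ≤ q``.
    """
    p = np.asarray(p_values, float).ravel()
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adj_sorted = np.minimum(adj_sorted, 1.0)
    adjusted = np.empty(m)
    adjusted[order] = adj_sorted
    reject = adjusted <= q
    return reject.reshape(np.shape(p_values)), adjusted.reshape(np.shape(p_values))


def bonferroni(p_values: np.ndarray, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Bonferroni correction: adjusted p = min(1, m·p)."""
    p = np.asarray(p_values, float)
    adjusted = np.minimum(1.0, p * p.size)
    return adjusted <= alpha, adjusted


@dataclass
class StatMap:
    """Element-wise paired-t results over an arbitrary comparison grid."""

    t: np.ndarray
    p_raw: np.ndarray
    p_adjusted: np.ndarray
    reject: np.ndarray
    method: str
    alpha: float
    df: int

    def __post_init__(self) -> None:
        shapes = {self.t.shape, self.p_raw.shape, self.p_adjusted.shape, self.reject.shape}
        if len(shapes) != 1:
            raise ValueError("StatMap fields must share one shape")
        if np.any(self.reject & (self.p_adjusted > self.alpha)):
            raise ValueError("rejections must have adjusted p <= alpha")


def paired_t_map(
    a: np.ndarray,
    b: np.ndarray,
    method: str = "bh_fdr",
    alpha: float = 0.05,
) -> StatMap:
    """Element-wise paired t over axis 0 (subjects), corrected family-wise.

    ``a`` and ``b`` are (subjects, ...) arrays paired along axis 0, e.g.
    per-subject mean band power on a frequency × time (× source) grid.
    """
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.shape != b.shape:
        raise ValueError("paired samples must share shape")
    n = a.shape[0]
    if n < 2:
        raise ValueError("need at least 2 subjects")
    d = a - b
    mean = d.mean(axis=0)
    sd = d.std(axis=0, ddof=1)
    df = n - 1
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(sd > 0, mean / (sd / np.sqrt(n)), np.where(mean == 0, 0.0, np.inf * np.sign(mean)))
    p = 2.0 * sp_stats.t.sf(np.abs(t), df)
    p = np.where(np.isinf(t), 0.0, p)
    if method == "bh_fdr":
        reject, adj = bh_fdr(p, alpha)
    elif method == "bonferroni":
        reject, adj = bonferroni(p, alpha)
    elif method == "none":
        adj = p.copy()
        reject = p <= alpha
    else:
        raise ValueError(f"unknown correction {method!r}")
    return StatMap(t=t, p_raw=p, p_adjusted=adj, reject=reject, method=method, alpha=alpha, df=df)


def rm_anova(values: np.ndarray, factor_names: tuple[str, ...] | None = None) -> dict:
    """Repeated-measures ANOVA on a complete within-subject table.

    ``values`` is (subjects × levels) for one factor or
    (subjects × levels1 × levels2) for two factors; each effect is
    tested against its effect × subject mean square.  Returns
    ``{effect: {"df": ..., "F": ..., "p": ...}}`` including the
    interaction for the two-way layout.
    """
    from statsmodels.stats.anova import AnovaRM

    values = np.asarray(values, float)
    if np.any(~np.isfinite(values)):
        raise ValueError("missing cells: repeated-measures table must be complete")
    if values.ndim == 2:
        ns, l1 = values.shape
        if ns < 2 or l1 < 2:
            raise ValueError("need >= 2 subjects and >= 2 levels")
        names = factor_names or ("factor",)
        rows = [
            {"subject": s, names[0]: i, "y": values[s, i]}
            for s in range(ns)
            for i in range(l1)
        ]
        within = [names[0]]
    elif values.ndim == 3:
        ns, l1, l2 = values.shape
        if ns < 2:
            raise ValueError("need >= 2 subjects")
        names = factor_names or ("factor1", "factor2")
        rows = [
            {"subject": s, names[0]: i, names[1]: j, "y": values[s, i, j]}
            for s in range(ns)
            for i in range(l1)
            for j in range(l2)
        ]
        within = list(names)
    else:
        raise ValueError("values must be subjects × levels (× levels)")
    if np.ptp(values) == 0.0:
        # degenerate: identical values everywhere -> F = 0 for each effect
        out = {}
        keys = within + ([f"{within[0]}:{within[1]}"] if len(within) == 2 else [])
        for k in keys:
            out[k] = {"df": np.nan, "F": 0.0, "p": 1.0}
        return out
    table = AnovaRM(pd.DataFrame(rows), depvar="y", subject="subject", within=within).fit().anova_table
    out = {}
    for effect, row in table.iterrows():
        out[effect] = {
            "df": (float(row["Num DF"]), float(row["Den DF"])),
            "F": float(row["F Value"]),
            "p": float(row["Pr > F"]),
        }
    return out


RETRIEVAL_CLASSES = ("remembered", "forgotten", "false_remembered")


def behavior_stats(behaviors: list[pd.DataFrame], alpha: float = 0.05) -> dict:
    """Behavioral report across subjects.

    Per subject: mean retrieval reaction time per outcome class and the
    fraction of encoding trials completed with an abstract/concrete
    judgment, split by later outcome.  Across subjects: a one-way
    repeated-measures ANOVA on the three retrieval reaction times with
    Bonferroni-corrected paired-t post-hocs, and a paired t on the
    judgment-completion proportions.
    """
    if len(behaviors) < 2:
        raise ValueError("behavioral ANOVA needs at least 2 subjects")
    from .synthgen import encoding_outcomes, retrieval_outcomes

    rt = np.empty((len(behaviors), len(RETRIEVAL_CLASSES)))
    judged = np.empty((len(behaviors), 2))  # remembered, forgotten
    for s, beh in enumerate(behaviors):
        ret = beh[beh["phase"] == "retrieval"].reset_index(drop=True)
        cls = retrieval_outcomes(beh)
        for k, c in enumerate(RETRIEVAL_CLASSES):
            sel = cls == c
            rt[s, k] = ret.loc[sel, "rt_ms"].mean() if sel.any() else np.nan
        enc = beh[beh["phase"] == "encoding"].reset_index(drop=True)
        out = encoding_outcomes(beh)
        for k, c in enumerate(("remembered", "forgotten")):
            sel = out == c
            judged[s, k] = (enc.loc[sel, "judgment"] != "NA").mean() if sel.any() else np.nan
    anova = rm_anova(rt, ("rt_class",))
    posthoc_raw = {}
    pairs = [(0, 1), (0, 2), (1, 2)]
    for i, j in pairs:
        t, p, df = paired_t(rt[:, i], rt[:, j])
        posthoc_raw[f"{RETRIEVAL_CLASSES[i]}_vs_{RETRIEVAL_CLASSES[j]}"] = (t, p, df)
    praw = np.array([v[1] for v in posthoc_raw.values()])
    reject, padj = bonferroni(praw, alpha)
    posthoc = {
        name: {"t": v[0], "p_raw": v[1], "p_adjusted": float(pa), "reject": bool(r), "df": v[2]}
        for (name, v), pa, r in zip(posthoc_raw.items(), padj, reject)
    }
    tj, pj, dfj = paired_t(judged[:, 0], judged[:, 1])
    return {
        "rt_means_ms": pd.DataFrame(rt, columns=list(RETRIEVAL_CLASSES)),
        "rt_anova": anova,
        "rt_posthoc": posthoc,
        "judgment_completion": pd.DataFrame(judged, columns=["remembered", "forgotten"]),
        "judgment_t": {"t": tj, "p": pj, "df": dfj},
    }


@dataclass
class HLRResult:
    """Hierarchical-regression comparison of nested designs per subject."""

    r2_base: np.ndarray
    r2_full: np.ndarray
    f_base: np.ndarray
    f_full: np.ndarray
    t_r2: float
    p_r2: float
    t_f: float
    p_f: float


def _ols_r2_f(y: np.ndarray, X: np.ndarray) -> tuple[float, float]:
    import statsmodels.api as sm

    model = sm.OLS(y, sm.add_constant(X, has_constant="add")).fit()
    f = float(model.fvalue) if np.isfinite(model.fvalue) else 0.0
    return float(model.rsquared), f

def hlr_compare(
    targets: np.ndarray,
    base_predictors: np.ndarray,
    added_predictors: np.ndarray,
) -> HLRResult:
    """Per-subject OLS of the base vs the base+added design.

    ``targets`` is (subjects, n_obs); predictors are
    (subjects, n_obs, p).  The full model nests the base by
    construction (its columns are base ∥ added).  Reports per-subject
    R² and overall F for both models and across-subject paired t-tests
    on R² and on F.  Rank-deficient designs (e.g. a duplicated column)
    are handled by the pseudo-inverse, leaving ΔR² = 0.
    """
    y = np.asarray(targets, float)
    Xb = np.asarray(base_predictors, float)
    Xa = np.asarray(added_predictors, float)
    ns, nobs = y.shape
    if Xb.shape[:2] != (ns, nobs) or Xa.shape[:2] != (ns, nobs):
        raise ValueError("predictors must align with targets per subject")
    p_full = Xb.shape[2] + Xa.shape[2]
    if nobs < p_full + 2:
        raise ValueError("need observations >= predictors + 2")
    r2b = np.empty(ns); r2f = np.empty(ns); fb = np.empty(ns); ff = np.empty(ns)
    for s in range(ns):
        r2b[s], fb[s] = _ols_r2_f(y[s], Xb[s])
        r2f[s], ff[s] = _ols_r2_f(y[s], np.hstack([Xb[s], Xa[s]]))
    # numerical guard: nesting guarantees r2_full >= r2_base
    r2f = np.maximum(r2f, r2b - 1e-12)
    t_r2, p_r2, _ = paired_t(r2b, r2f)
    t_f, p_f, _ = paired_t(fb, ff)
    return HLRResult(r2_base=r2b, r2_full=r2f, f_base=fb, f_full=ff,
                     t_r2=t_r2, p_r2=p_r2, t_f=t_f, p_f=p_f)
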