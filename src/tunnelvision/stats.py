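"""Statistical layer for grouped flight metrics and scene magnitudes.

Three families of procedures:

1. Condition comparisons of flight metrics: a residual-normality gate
   chooses between one-way ANOVA with Tukey-Kramer post hocs and a
   Kruskal-Wallis test with a Tukey-type (Nemenyi) comparison on mean
   ranks; either way the pairwise decisions are summarised as a compact
   letter display (groups sharing no letter differ at alpha).
2. Pairwise Brown-Forsythe tests on group variances, quantifying how
   tightly flights centre around their median position.
3. The habitat x quadrant linear mixed model
   ``magnitude ~ habitat * quadrant + (1 | scene)`` with scene random
   intercepts, fitted by maximum likelihood so AIC/deviance are comparable
   across fixed-effect structures, followed by Tukey-adjusted pairwise
   contrasts of estimated marginal means.

All tests default to alpha = 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps
import statsmodels.formula.api as smf

from .specs import StatsDesign

__all__ = [
    "StatResult",
    "LmmResult",
    "residual_normality_gate",
    "omnibus_and_posthoc",
    "pairwise_brown_forsythe",
    "compact_letter_display",
    "fit_lmm",
    "lmm_pairwise",
]


def _split_groups(values, groups):
    values = np.asarray(values, dtype=float)
    groups = np.asarray(groups)
    names = sorted(pd.unique(groups).tolist())
    return values, groups, names, [values[groups == g] for g in names]


@dataclass
class StatResult:
    """Outcome of an omnibus test plus pairwise post hocs."""

    test: str
    statistic: float
    df: tuple
    p: float
    pairwise_p: pd.DataFrame
    letters: dict
    alpha: float
    choice: str  # "parametric" or "nonparametric"


def residual_normality_gate(values, groups, alpha: float = 0.05) -> str:
    """Choose the test family from the normality of pooled residuals.

    Residuals are deviations from group means; a Shapiro-Wilk test on the
    pooled residuals with p >= alpha confirms normality ("parametric"),
    otherwise the nonparametric path is taken.  A constant-valued group
    forces the nonparametric path (its residual distribution is
    degenerate).
    """
    values, groups, names, samples = _split_groups(values, groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    for name, s in zip(names, samples):
        if len(s) < 3:
            raise ValueError(f"group {name!r} has < 3 values")
    if any(np.ptp(s) == 0 for s in samples):
        warnings.warn("constant-valued group: falling back to nonparametric tests")
        return "nonparametric"
    residuals = np.concatenate([s - s.mean() for s in samples])
    _, p = sps.shapiro(residuals)
    return "parametric" if p >= alpha else "nonparametric"


def _tukey_kramer_anova(samples, names):
    """Tukey-Kramer pairwise p-values after one-way ANOVA (unequal n honoured)."""
    k = len(names)
    n_total = sum(len(s) for s in samples)
    df_w = n_total - k
    mse = sum(((s - s.mean()) ** 2).sum() for s in samples) / df_w
    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i, j in combinations(range(k), 2):
        se = np.sqrt(mse / 2.0 * (1.0 / len(samples[i]) + 1.0 / len(samples[j])))
        q = abs(samples[i].mean() - samples[j].mean()) / se
        p = sps.studentized_range.sf(q, k, df_w)
        pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return pmat


def _tukey_on_ranks(values, groups, names):
    """Tukey-type (Nemenyi) multiple comparison on mean ranks.

    Uses the studentised-range distribution on standardised rank-mean
    differences with the usual tie correction — the standard reading of
    "Kruskal-Wallis with Tukey-Kramer-corrected post hocs".
    """
    ranks = sps.rankdata(values)
    n_total = len(values)
    _, counts = np.unique(values, return_counts=True)
    tie_corr = 1.0 - (counts**3 - counts).sum() / (n_total**3 - n_total)
    var = n_total * (n_total + 1) / 12.0 * tie_corr
    k = len(names)
    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    for i, j in combinations(range(k), 2):
        ri = ranks[groups == names[i]]
        rj = ranks[groups == names[j]]
        se = np.sqrt(var * (1.0 / len(ri) + 1.0 / len(rj)))
        q = np.sqrt(2.0) * abs(ri.mean() - rj.mean()) / se
        p = sps.studentized_range.sf(q, k, np.inf)
        pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return pmat


def omnibus_and_posthoc(
    values, groups, choice: str | None = None, alpha: float = 0.05
) -> StatResult:
    """Omnibus group comparison with Tukey-family post hocs and letters.

    ``choice`` is normally the output of :func:`residual_normality_gate`;
    if omitted the gate is applied first.
    """
    values, groups, names, samples = _split_groups(values, groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    if choice is None:
        choice = residual_normality_gate(values, groups, alpha)
    if choice == "parametric":
        stat, p = sps.f_oneway(*samples)
        k = len(names)
        n_total = len(values)
        df = (k - 1, n_total - k)
        pmat = _tukey_kramer_anova(samples, names)
        test = "anova_tukey_kramer"
    else:
        stat, p = sps.kruskal(*samples)
        df = (len(names) - 1,)
        pmat = _tukey_on_ranks(values, groups, names)
        test = "kruskal_wallis_tukey_ranks"
    letters = compact_letter_display(pmat, alpha)
    return StatResult(
        test=test,
        statistic=float(stat),
        df=df,
        p=float(p),
        pairwise_p=pmat,
        letters=letters,
        alpha=alpha,
        choice=choice,
    )


def pairwise_brown_forsythe(
    values, groups, alpha: float = 0.05, adjust: str | None = None
) -> tuple[pd.DataFrame, dict]:
    """Pairwise Brown-Forsythe variance tests with a compact letter display.

    Each pair of groups is compared with the Brown-Forsythe statistic
    (one-way ANOVA on absolute deviations from group medians), used here as
    a measure of how strongly flights centre.  P-values are reported
    uncorrected by default; ``adjust="holm"`` applies a Holm step-down
    correction across the family.
    """
    values, groups, names, samples = _split_groups(values, groups)
    if len(names) < 2:
        raise ValueError("need >= 2 groups")
    for name, s in zip(names, samples):
        if len(s) < 2:
            raise ValueError(f"group {name!r} has < 2 values")
    k = len(names)
    pmat = pd.DataFrame(np.ones((k, k)), index=names, columns=names)
    pairs, raw = [], []
    for i, j in combinations(range(k), 2):
        a, b = samples[i], samples[j]
        dev = np.concatenate([np.abs(a - np.median(a)), np.abs(b - np.median(b))])
        if np.ptp(dev) == 0:  # identical spreads (e.g. identical samples)
            p = 1.0
        else:
            _, p = sps.levene(a, b, center="median")
        pairs.append((i, j))
        raw.append(p)
    if adjust == "holm":
        order = np.argsort(raw)
        m = len(raw)
        adj, running = [0.0] * m, 0.0
        for rank, idx in enumerate(order):
            running = max(running, min(1.0, (m - rank) * raw[idx]))
            adj[idx] = running
        raw = adj
    elif adjust is not None:
        raise ValueError(f"unknown adjustment {adjust!r}")
    for (i, j), p in zip(pairs, raw):
        pmat.iloc[i, j] = pmat.iloc[j, i] = p
    return pmat, compact_letter_display(pmat, alpha)


def compact_letter_display(pairwise_p: pd.DataFrame, alpha: float = 0.05) -> dict:
    """Assign letters so two groups share a letter iff they do not differ.

    Insert-and-absorb algorithm: start with one letter covering all
    groups; for each significant pair, split every letter containing both
    members, then absorb redundant letters.  Groups are processed in
    canonical (sorted) order, so the labelling is independent of input
    order.
    """
    if not np.allclose(pairwise_p.values, pairwise_p.values.T, equal_nan=True):
        raise ValueError("pairwise p matrix must be symmetric")
    names = sorted(pairwise_p.index.tolist())
    p = pairwise_p.loc[names, names]
    letter_sets: list[set] = [set(names)]
    for a, b in combinations(names, 2):
        if p.loc[a, b] < alpha:
            new_sets = []
            for s in letter_sets:
                if a in s and b in s:
                    new_sets.extend([s - {a}, s - {b}])
                else:
                    new_sets.append(s)
            # absorb: drop empty sets, duplicates and sets contained in another
            uniq: list[set] = []
            for s in new_sets:
                if s and s not in uniq:
                    uniq.append(s)
            letter_sets = [s for s in uniq if not any(s < t for t in uniq)]
    # order letters by their first member for a stable display
    letter_sets.sort(key=lambda s: tuple(sorted(s)))
    alphabet = "abcdefghijklmnopqrstuvwxyz"
    out = {name: "" for name in names}
    for letter, s in zip(alphabet, letter_sets):
        for name in sorted(s):
            out[name] += letter
    return out


# ---------------------------------------------------------------------------
# Linear mixed model: magnitude ~ habitat * quadrant + (1 | scene)


@dataclass
class LmmResult:
    """Maximum-likelihood mixed-model fit with its reduced-model comparison."""

    fixed_effects: pd.Series
    fixed_se: pd.Series
    scene_variance: float
    residual_variance: float
    llf: float
    aic: float
    deviance: float
    model_aics: dict
    model_deviances: dict
    full_model_preferred: bool
    singular: bool
    design: StatsDesign
    result: object = field(repr=False, default=None)
    table: pd.DataFrame = field(repr=False, default=None)


def _ml_fit(formula: str, table: pd.DataFrame, group_col: str):
    res = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = smf.mixedlm(formula, table, groups=table[group_col])
        # optimisers occasionally yield a singular Hessian; fall through
        for method in ("lbfgs", "bfgs", "powell", "cg", "nm"):
            try:
                cand = model.fit(reml=False, method=method)
            except np.linalg.LinAlgError:
                continue
            if np.isfinite(cand.llf) and np.all(np.isfinite(cand.fe_params)):
                res = cand
                break
    if res is None:
        raise np.linalg.LinAlgError(f"mixed-model fit failed for {formula!r}")
    k = res.k_fe + 2  # fixed effects + scene variance + residual variance
    aic = 2 * k - 2 * res.llf
    return res, aic, -2 * res.llf


def fit_lmm(table: pd.DataFrame, design: StatsDesign) -> LmmResult:
    """Fit ``magnitude ~ habitat * quadrant + (1 | scene)`` by ML.

    Also fits the null model (intercept + random intercept) and the two
    single-factor models, and flags whether the full model attains the
    lowest AIC and deviance — the gate applied before pairwise post hocs.
    ML (not REML) keeps AIC/deviance comparable across fixed-effect
    structures.  A singular fit (scene variance collapsing to zero) is
    retained but flagged.
    """
    resp, grp = design.response, design.random_group
    scenes = table.groupby("habitat")[grp].nunique()
    if (scenes < 2).any() or table[grp].nunique() < 2:
        raise ValueError("need >= 2 scenes per habitat for a random intercept")
    cells = table.groupby(["habitat", "quadrant"]).size()
    if len(cells) < len(design.habitats) * len(design.quadrants):
        raise ValueError("incomplete habitat x quadrant crossing")

    formulas = {
        "full": f"{resp} ~ C(habitat) * C(quadrant)",
        "habitat": f"{resp} ~ C(habitat)",
        "quadrant": f"{resp} ~ C(quadrant)",
        "null": f"{resp} ~ 1",
    }
    fits = {name: _ml_fit(f, table, grp) for name, f in formulas.items()}
    res, aic, deviance = fits["full"]
    aics = {name: a for name, (_, a, _) in fits.items()}
    deviances = {name: d for name, (_, _, d) in fits.items()}
    preferred = all(aic <= a for a in aics.values()) and all(
        deviance <= d for d in deviances.values()
    )
    scene_var = float(res.cov_re.iloc[0, 0])
    singular = scene_var < 1e-8 * res.scale
    return LmmResult(
        fixed_effects=res.fe_params,
        fixed_se=res.bse_fe,
        scene_variance=scene_var,
        residual_variance=float(res.scale),
        llf=float(res.llf),
        aic=aic,
        deviance=deviance,
        model_aics=aics,
        model_deviances=deviances,
        full_model_preferred=preferred,
        singular=singular,
        design=design,
        result=res,
        table=table,
    )


def _stars(p: float) -> str:
    return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""


def lmm_pairwise(lmm: LmmResult, design: StatsDesign | None = None) -> pd.DataFrame:
    """Tukey-adjusted pairwise contrasts of estimated marginal means.

    Marginal means per habitat (averaged over quadrants with equal
    weights) and per quadrant (averaged over habitats) are contrasted
    within each factor's margin; each family is adjusted with the
    studentised-range (Tukey) distribution.  Degrees of freedom use a
    containment-style approximation: between-scene contrasts (habitat) use
    ``n_scenes - n_habitats``; within-scene contrasts (quadrant) use
    ``(n_scenes - n_habitats) * (n_quadrants - 1)``.
    """
    design = design or lmm.design
    res, table = lmm.result, lmm.table
    if res is None:
        raise ValueError("LmmResult carries no fitted model")
    habs = [h for h in design.habitats if h in set(table["habitat"])]
    quads = [q for q in design.quadrants if q in set(table["quadrant"])]
    if len(habs) < 2 or len(quads) < 2:
        raise ValueError("pairwise contrasts need >= 2 levels per factor")

    design_info = res.model.data.design_info
    from patsy import dmatrix

    grid = pd.DataFrame(
        [(h, q) for h in habs for q in quads], columns=["habitat", "quadrant"]
    )
    x_cells = np.asarray(dmatrix(design_info, grid))
    cell_index = {(h, q): i for i, (h, q) in enumerate(zip(grid["habitat"], grid["quadrant"]))}

    beta = np.asarray(res.fe_params)
    cov = np.asarray(res.cov_params())[: len(beta), : len(beta)]
    n_scenes = table[design.random_group].nunique()
    df_between = max(n_scenes - len(habs), 1)
    df_within = max((n_scenes - len(habs)) * (len(quads) - 1), 1)

    rows = []
    for factor, levels, other, df in (
        ("habitat", habs, quads, df_between),
        ("quadrant", quads, habs, df_within),
    ):
        k = len(levels)
        for a, b in combinations(levels, 2):
            L = np.zeros(len(beta))
            for o in other:
                ia = cell_index[(a, o) if factor == "habitat" else (o, a)]
                ib = cell_index[(b, o) if factor == "habitat" else (o, b)]
                L += (x_cells[ia] - x_cells[ib]) / len(other)
            est = float(L @ beta)
            se = float(np.sqrt(L @ cov @ L))
            t = est / se if se > 0 else np.inf
            p = float(sps.studentized_range.sf(np.sqrt(2.0) * abs(t), k, df))
            rows.append(
                {
                    "factor": factor,
                    "level_a": a,
                    "level_b": b,
                    "estimate": est,
                    "se": se,
                    "t": t,
                    "df": df,
                    "p_tukey": p,
                    "stars": _stars(p),
                }
            )
    return pd.DataFrame(rows)
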