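"""Inferential statistics for repeated-measures localisation designs.

Implements the analyses the study design calls for: paired and
one-sample t-tests, balanced repeated-measures ANOVA with up to two
within-subject factors and an optional between-subject factor
(split-plot decomposition), Mauchly's sphericity test with
Greenhouse-Geisser (GG) degrees-of-freedom correction per within
effect, Bonferroni-adjusted post-hoc comparisons, and a battery that
strings these together over the estimation module's summary tables.

The ANOVA uses the classical univariate sums-of-squares decomposition
for balanced designs: each within effect (and its interaction with the
between factor) is tested against its own effect-by-subject
interaction; the between effect is tested against subjects within
groups.  GG epsilon for a k-level within effect is computed from the
pooled covariance of orthonormal contrast scores,

    epsilon = (sum lambda)^2 / ((k-1) * sum lambda^2),

bounded in [1/(k-1), 1]; corrected p-values use epsilon-scaled
numerator and denominator dfs.  Corrected values are reported always
and flagged for use when Mauchly's test rejects at 0.05, mirroring
conventional conditional reporting.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "TTestResult",
    "MauchlyGG",
    "PosthocSet",
    "paired_t_test",
    "one_sample_t_test",
    "mauchly_and_gg",
    "rm_anova",
    "bonferroni",
    "analysis_battery",
]


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    df: int
    p_value: float
    mean_difference: float
    paired: bool

    def to_dict(self) -> dict:
        return {
            "t": self.t_statistic, "df": self.df, "p": self.p_value,
            "mean_difference": self.mean_difference, "paired": self.paired,
        }


@dataclass(frozen=True)
class MauchlyGG:
    mauchly_w: float
    mauchly_chi2: float
    mauchly_df: int
    mauchly_p: float
    gg_epsilon: float


@dataclass(frozen=True)
class PosthocSet:
    """Pairwise comparisons with Bonferroni family adjustment."""

    comparisons: list = field(default_factory=list)
    family_size: int = 0

    def to_records(self) -> list[dict]:
        return [dict(c) for c in self.comparisons]


def paired_t_test(a, b, tail: str = "two-sided") -> TTestResult:
    """Paired t-test on per-participant values (df = n - 1)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired samples must have equal length")
    if a.size < 2:
        raise ValueError("need at least two pairs")
    d = a - b
    if d.std(ddof=1) == 0:  # identical pairs: no evidence either way
        t = 0.0 if d.mean() == 0 else math.copysign(math.inf, d.mean())
        return TTestResult(t, a.size - 1, 1.0 if t == 0 else 0.0,
                           float(d.mean()), paired=True)
    res = sps.ttest_rel(a, b, alternative=tail)
    return TTestResult(float(res.statistic), a.size - 1, float(res.pvalue),
                       float(np.mean(a - b)), paired=True)


def one_sample_t_test(values, popmean: float = 0.0,
                      tail: str = "two-sided") -> TTestResult:
    values = np.asarray(values, dtype=float)
    res = sps.ttest_1samp(values, popmean, alternative=tail)
    return TTestResult(float(res.statistic), values.size - 1, float(res.pvalue),
                       float(values.mean() - popmean), paired=False)


def _orthonormal_contrasts(k: int) -> np.ndarray:
    """k x (k-1) orthonormal contrast matrix (columns sum to zero)."""
    h = np.zeros((k, k - 1))
    for j in range(1, k):
        h[:j, j - 1] = 1.0
        h[j, j - 1] = -j
        h[:, j - 1] /= np.sqrt(j * (j + 1))
    return h


def _contrast_cov(scores: np.ndarray, groups: np.ndarray) -> np.ndarray:
    """Covariance of contrast scores pooled within between-subject groups."""
    n, _ = scores.shape
    resid = scores.copy()
    glabels = np.unique(groups)
    for g in glabels:
        mask = groups == g
        resid[mask] -= scores[mask].mean(axis=0)
    return resid.T @ resid / (n - glabels.size)


def mauchly_and_gg(data, groups=None) -> MauchlyGG:
    """Mauchly's sphericity test and GG epsilon for an n x k score matrix.

    ``data`` holds one score per subject (rows) and within-factor level
    (columns); ``groups`` optionally assigns subjects to between-subject
    groups (covariance is then pooled within groups).  For k = 2 the
    sphericity assumption is vacuous: epsilon = 1, chi2 = 0.
    """
    y = np.asarray(data, dtype=float)
    n, k = y.shape
    if k < 2:
        raise ValueError("need at least two within-factor levels")
    if groups is None:
        groups = np.zeros(n, dtype=int)
    groups = np.asarray(groups)
    n_groups = np.unique(groups).size
    if n - n_groups < k - 1:
        raise ValueError("too few subjects for a full-rank contrast covariance")

    scores = y @ _orthonormal_contrasts(k)
    return _mauchly_gg_from_scores(scores, groups)


def _mauchly_gg_from_scores(scores: np.ndarray, groups: np.ndarray) -> MauchlyGG:
    n, d = scores.shape
    n_groups = np.unique(groups).size
    n_eff = n - n_groups  # error df for the covariance
    if d == 1:
        return MauchlyGG(1.0, 0.0, 0, 1.0, 1.0)
    s = _contrast_cov(scores, groups)
    eig = np.linalg.eigvalsh(s)
    tr = eig.sum()
    if tr <= 0 or np.any(eig < -1e-10 * abs(tr)):
        raise ValueError("singular or non-PSD contrast covariance")
    eig = np.clip(eig, 0.0, None)
    eps = tr**2 / (d * np.sum(eig**2))
    eps = float(np.clip(eps, 1.0 / d, 1.0))

    det = float(np.prod(eig))
    w = det / (tr / d) ** d
    w = min(max(w, np.finfo(float).tiny), 1.0)
    f_corr = 1.0 - (2 * d**2 + d + 2) / (6.0 * d * n_eff)
    chi2 = -f_corr * n_eff * np.log(w)
    df = d * (d + 1) // 2 - 1
    p = float(sps.chi2.sf(chi2, df)) if df > 0 else 1.0
    return MauchlyGG(float(w), float(chi2), df, p, eps)


def _check_balanced(df, subject, factors):
    counts = df.groupby([subject, *factors], observed=True).size()
    full = np.prod([df[f].nunique() for f in factors])
    n_subj = df[subject].nunique()
    if len(counts) != n_subj * full or counts.nunique() != 1 or counts.iloc[0] != 1:
        raise ValueError(
            "design must be balanced with exactly one value per "
            "subject x within-cell; aggregate to cell means first")


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    subject: str,
    within: list[str],
    between: str | None = None,
) -> pd.DataFrame:
    """Balanced repeated-measures / split-plot ANOVA.

    ``within`` lists one or two within-subject factors; ``between``
    optionally names a between-subject factor (subjects nested in its
    levels).  Returns one row per effect with uncorrected and
    GG-corrected statistics::

        effect, ss, df1, df2, ms, F, p,
        gg_epsilon, df1_gg, df2_gg, p_gg,
        mauchly_w, mauchly_chi2, mauchly_p, sphericity_met, use_gg

    Missing cells or replicated cells raise; no silent imputation.
    """
    if not 1 <= len(within) <= 2:
        raise ValueError("within must list one or two factors")
    cols = [subject, dv, *within] + ([between] if between else [])
    missing = set(cols) - set(data.columns)
    if missing:
        raise ValueError(f"data lacks columns {sorted(missing)}")
    df = data[cols].dropna()
    _check_balanced(df, subject, within)
    if between is not None:
        per_subj = df.groupby(subject, observed=True)[between].nunique()
        if (per_subj != 1).any():
            raise ValueError("each subject must sit in exactly one between level")

    subjects = np.sort(df[subject].unique())
    a_levels = np.sort(df[within[0]].unique())
    b_levels = np.sort(df[within[1]].unique()) if len(within) == 2 else np.array([0])
    n, a, b = len(subjects), len(a_levels), len(b_levels)

    wide = df.set_index([subject, *within])[dv]
    y = np.empty((n, a, b))
    for i, s in enumerate(subjects):
        for j, al in enumerate(a_levels):
            if len(within) == 2:
                for k, bl in enumerate(b_levels):
                    y[i, j, k] = wide.loc[(s, al, bl)]
            else:
                y[i, j, 0] = wide.loc[(s, al)]

    if between is not None:
        gmap = df.groupby(subject, observed=True)[between].first()
        glabels = np.sort(gmap.unique())
        groups = np.searchsorted(glabels, gmap.loc[subjects].to_numpy())
        g = len(glabels)
    else:
        groups = np.zeros(n, dtype=int)
        g = 1

    rows = _split_plot(y, groups, g)
    token_map = {"A": within[0], "G": between or "G"}
    if len(within) == 2:
        token_map["B"] = within[1]
    for eff in rows:
        eff["effect"] = "*".join(token_map[t] for t in eff["effect"].split("*"))
    res = pd.DataFrame(rows)
    res["sphericity_met"] = res["mauchly_p"] >= 0.05
    res["use_gg"] = ~res["sphericity_met"]
    return res


def _split_plot(y: np.ndarray, groups: np.ndarray, g: int) -> list[dict]:
    """Sums-of-squares decomposition on cell means y[subject, a, b]."""
    n, a, b = y.shape
    ng = np.bincount(groups, minlength=g).astype(float)

    M = y.mean()
    m_subj = y.mean(axis=(1, 2))
    m_a = y.mean(axis=(0, 2))
    m_b = y.mean(axis=(0, 1))
    m_ab = y.mean(axis=0)
    m_g = np.array([y[groups == h].mean() for h in range(g)])
    m_ag = np.stack([y[groups == h].mean(axis=(0, 2)) for h in range(g)], axis=1)
    m_bg = np.stack([y[groups == h].mean(axis=(0, 1)) for h in range(g)], axis=1)
    m_abg = np.stack([y[groups == h].mean(axis=0) for h in range(g)], axis=2)
    m_sa = y.mean(axis=2)
    m_sb = y.mean(axis=1)

    ss_g = a * b * float(np.sum(ng * (m_g - M) ** 2))
    ss_s = a * b * float(np.sum((m_subj - m_g[groups]) ** 2))
    ss_a = b * n * float(np.sum((m_a - M) ** 2))
    ss_ag = b * float(np.sum(ng[None, :] * (m_ag - m_a[:, None] - m_g[None, :] + M) ** 2))
    ss_as = b * float(np.sum(
        (m_sa - m_subj[:, None] - m_ag[:, groups].T + m_g[groups, None]) ** 2))
    ss_b = a * n * float(np.sum((m_b - M) ** 2))
    ss_bg = a * float(np.sum(ng[None, :] * (m_bg - m_b[:, None] - m_g[None, :] + M) ** 2))
    ss_bs = a * float(np.sum(
        (m_sb - m_subj[:, None] - m_bg[:, groups].T + m_g[groups, None]) ** 2))
    ss_ab = n * float(np.sum((m_ab - m_a[:, None] - m_b[None, :] + M) ** 2))
    ss_abg = float(np.sum(
        ng[None, None, :] * (m_abg - m_ag[:, None, :] - m_bg[None, :, :]
                             - m_ab[:, :, None] + m_a[:, None, None]
                             + m_b[None, :, None] + m_g[None, None, :] - M) ** 2))
    ss_total = float(np.sum((y - M) ** 2))
    ss_abs = ss_total - (ss_g + ss_s + ss_a + ss_ag + ss_as + ss_b + ss_bg
                         + ss_bs + ss_ab + ss_abg)
    ss_abs = max(ss_abs, 0.0)

    no_sph = MauchlyGG(1.0, 0.0, 0, 1.0, 1.0)

    def _sphericity(scores):
        # too few subjects (or degenerate data) leave the contrast
        # covariance singular; report no correction rather than fail
        try:
            return _mauchly_gg_from_scores(scores, groups)
        except ValueError:
            return no_sph

    c_a = _orthonormal_contrasts(a)
    sph_a = _sphericity(y.mean(axis=2) @ c_a) if a > 1 else no_sph

    effects: list[dict] = []

    def add(name, ss, df1, ss_err, df2, sph: MauchlyGG):
        ms, ms_err = ss / df1, ss_err / df2
        F = ms / ms_err if ms_err > 0 else np.inf
        eps = sph.gg_epsilon
        effects.append({
            "effect": name, "ss": ss, "df1": df1, "df2": df2, "ms": ms,
            "F": F, "p": float(sps.f.sf(F, df1, df2)),
            "gg_epsilon": eps, "df1_gg": eps * df1, "df2_gg": eps * df2,
            "p_gg": float(sps.f.sf(F, eps * df1, eps * df2)),
            "mauchly_w": sph.mauchly_w, "mauchly_chi2": sph.mauchly_chi2,
            "mauchly_p": sph.mauchly_p,
        })

    if g > 1:
        add("G", ss_g, g - 1, ss_s, n - g, no_sph)
    add("A", ss_a, a - 1, ss_as, (a - 1) * (n - g), sph_a)
    if g > 1:
        add("A*G", ss_ag, (a - 1) * (g - 1), ss_as, (a - 1) * (n - g), sph_a)
    if b > 1:
        c_b = _orthonormal_contrasts(b)
        sph_b = _sphericity(y.mean(axis=1) @ c_b)
        c_ab = np.einsum("ap,bq->abpq", c_a, c_b).reshape(a * b, (a - 1) * (b - 1))
        sph_ab = _sphericity(y.reshape(n, a * b) @ c_ab)
        add("B", ss_b, b - 1, ss_bs, (b - 1) * (n - g), sph_b)
        if g > 1:
            add("B*G", ss_bg, (b - 1) * (g - 1), ss_bs, (b - 1) * (n - g), sph_b)
        add("A*B", ss_ab, (a - 1) * (b - 1), ss_abs, (a - 1) * (b - 1) * (n - g), sph_ab)
        if g > 1:
            add("A*B*G", ss_abg, (a - 1) * (b - 1) * (g - 1), ss_abs,
                (a - 1) * (b - 1) * (n - g), sph_ab)
    return effects


def bonferroni(p_values, family_size: int | None = None) -> PosthocSet:
    """Bonferroni adjustment: p_adj = min(1, m * p), ordering preserved."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p) if family_size is None else family_size
    if m < len(p):
        raise ValueError("family size smaller than number of comparisons")
    comps = [{"raw_p": float(pi), "adjusted_p": float(min(1.0, m * pi))} for pi in p]
    return PosthocSet(comps, m)


def _pairwise_phase_posthoc(wide: pd.DataFrame, labels) -> list[dict]:
    """All pairwise paired t-tests across columns, Bonferroni over the family."""
    pairs = list(itertools.combinations(labels, 2))
    raw = []
    out = []
    for x, ycol in pairs:
        tt = paired_t_test(wide[x], wide[ycol])
        raw.append(tt.p_value)
        out.append({"pair": f"{x} vs {ycol}", **tt.to_dict()})
    adj = bonferroni(raw, family_size=len(pairs))
    for rec, comp in zip(out, adj.comparisons):
        rec["bonferroni_p"] = comp["adjusted_p"]
    return out


def _paired_wide(means: pd.DataFrame, value: str, index: str, columns: str,
                 query: str) -> pd.DataFrame:
    sub = means.query(query)
    wide = sub.pivot_table(index=index, columns=columns, values=value)
    if wide.isna().any().any():
        raise ValueError(f"incomplete design for {query!r}")
    return wide


def analysis_battery(summaries: pd.DataFrame,
                     means: pd.DataFrame | None = None) -> dict:
    """Run the study's full set of planned analyses on summary tables.

    Needs per-location summaries (from ``summarize_conditions``) and the
    across-location means (computed here if absent).  Returns a nested,
    JSON-serialisable report keyed by analysis:

    - before-training paired t-tests on variability and bias for the
      auditory (A2 vs A1) and visual (V2 vs V1) reliability pairs;
    - reliability x azimuth repeated-measures ANOVAs on bias and
      variability, separately for audition and vision (before phase);
    - phase x feedback mixed ANOVAs on bias and variability of the
      trained stimulus (A2), with Bonferroni pairwise phase post-hocs;
    - before/after x feedback ANOVAs for the untrained stimulus (A1);
    - phase x stimulus x feedback ANOVAs comparing A1 and A2 change;
    - one-sample t-tests of post-training bias against zero.
    """
    from .estimation import mean_summaries as _mean_summaries

    if means is None:
        means = _mean_summaries(summaries)
    for phase in ("before", "training", "after"):
        if phase not in set(means["phase"]):
            raise ValueError(f"summaries lack phase {phase!r}")

    report: dict = {}

    # -- before-training reliability t-tests -------------------------------
    before = means.query("phase == 'before'")
    tt = {}
    for label, pair, value in [
        ("auditory_variability", ("A2", "A1"), "mean_variability"),
        ("visual_variability", ("V2", "V1"), "mean_variability"),
        ("auditory_bias", ("A2", "A1"), "mean_bias"),
        ("visual_bias", ("V2", "V1"), "mean_bias"),
    ]:
        wide = _paired_wide(means, value, "participant_id", "condition",
                            f"phase == 'before' and condition in {list(pair)}")
        tt[label] = paired_t_test(wide[pair[0]], wide[pair[1]]).to_dict()
    report["before_training_t_tests"] = tt

    # -- reliability x azimuth ANOVAs --------------------------------------
    sub = summaries.query("phase == 'before'")
    anovas = {}
    for label, conds, value in [
        ("auditory_variability", ("A1", "A2"), "fitted_sigma"),
        ("visual_variability", ("V1", "V2"), "fitted_sigma"),
        ("auditory_bias", ("A1", "A2"), "bias"),
        ("visual_bias", ("V1", "V2"), "bias"),
    ]:
        d = sub[sub["condition"].isin(conds)].rename(
            columns={"condition": "reliability", "location": "azimuth"})
        anovas[label] = rm_anova(
            d, dv=value, subject="participant_id",
            within=["reliability", "azimuth"]).to_dict("records")
    report["reliability_by_azimuth_anovas"] = anovas

    # -- trained stimulus (A2) across phases -------------------------------
    a2 = means.query("stimulus == 'A2'")
    trained = {}
    for label, value in [("bias", "mean_bias"), ("variability", "mean_variability")]:
        res = rm_anova(a2, dv=value, subject="participant_id",
                       within=["phase"], between="feedback_group")
        wide = a2.pivot_table(index="participant_id", columns="phase", values=value)
        trained[label] = {
            "anova": res.to_dict("records"),
            "posthoc_phases": _pairwise_phase_posthoc(
                wide, ["before", "training", "after"]),
        }
    report["trained_stimulus_phase_anovas"] = trained

    # -- untrained stimulus (A1), before vs after --------------------------
    a1 = means.query("stimulus == 'A1'")
    report["untrained_stimulus_phase_anovas"] = {
        label: rm_anova(a1, dv=value, subject="participant_id",
                        within=["phase"], between="feedback_group").to_dict("records")
        for label, value in [("bias", "mean_bias"),
                             ("variability", "mean_variability")]
    }

    # -- phase x stimulus x feedback ---------------------------------------
    both = means.query("stimulus in ['A1', 'A2'] and phase in ['before', 'after']")
    report["phase_by_stimulus_anovas"] = {
        label: rm_anova(both, dv=value, subject="participant_id",
                        within=["phase", "stimulus"],
                        between="feedback_group").to_dict("records")
        for label, value in [("bias", "mean_bias"),
                             ("variability", "mean_variability")]
    }

    # -- post-training bias vs zero ----------------------------------------
    after = means.query("phase == 'after'")
    report["posttraining_bias_vs_zero"] = {
        stim: one_sample_t_test(
            after.query("stimulus == @stim")["mean_bias"]).to_dict()
        for stim in ("A1", "A2")
    }
    return report
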