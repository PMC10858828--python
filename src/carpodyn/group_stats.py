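"""Group statistics: subject-blocked two-way ANOVA, Tukey posthoc tests
and the paired-design sample-size computation.

The group-wise comparison of joint widths across the range of motion is a
split-plot (mixed) design: ligament condition is a between-subject factor,
the wrist-angle bin a within-subject factor, and the subject a blocking
(random-intercept) factor nested in group.  On subject-by-bin cell means
the classical sums-of-squares decomposition is exact for balanced designs;
unbalanced group sizes are handled by unweighted (cell-mean) averaging
with the harmonic mean of the group sizes.  The group effect is tested
against the subject-within-group stratum, the bin and interaction effects
against the residual (bin x subject) stratum.

Pairwise group contrasts use Tukey's studentized-range adjustment on the
blocked ANOVA's error term.  The sample-size computation inverts the
noncentral-t power of a paired t test: for a standardized paired effect
size d the test statistic follows a noncentral t distribution with
df = n - 1 and noncentrality d * sqrt(n).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

DEFAULT_ALPHA = 0.01


# --------------------------------------------------------------------------
# Power / sample size (noncentral t)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class PowerSpec:
    """Design parameters of a paired t-test power computation."""

    alpha: float = 0.01
    power: float = 0.8
    effect_size: float = 1.4   # mean paired difference / SD of differences
    tails: int = 2

    def __post_init__(self):
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if not 0 < self.power < 1:
            raise ValueError("power must lie in (0, 1)")
        if self.effect_size <= 0:
            raise ValueError("effect size must be positive")
        if self.tails not in (1, 2):
            raise ValueError("tails must be 1 or 2")


def noncentral_t_power(n: int, d: float, alpha: float = 0.01,
                       tails: int = 2) -> float:
    """Power of a paired t test with n pairs and standardized effect d.

    P(|T'| > t_{1-alpha/tails, n-1}) where T' is noncentral t with
    df = n - 1 and noncentrality d * sqrt(n).  With d = 0 this equals
    alpha exactly; power is monotone increasing in n and d.
    """
    if n < 2:
        raise ValueError("need at least 2 pairs")
    if tails not in (1, 2):
        raise ValueError("tails must be 1 or 2")
    df = n - 1
    tcrit = stats.t.ppf(1.0 - alpha / tails, df)
    ncp = d * np.sqrt(n)
    power = float(stats.nct.sf(tcrit, df, ncp))
    if tails == 2:
        other = float(stats.nct.cdf(-tcrit, df, ncp))
        if np.isfinite(other):  # numerically ~0 far in the opposite tail
            power += other
    return min(power, 1.0)


def paired_sample_size(spec: PowerSpec | None = None, *, alpha: float = 0.01,
                       power: float = 0.8, effect_size: float = 1.4,
                       tails: int = 2, n_max: int = 10_000) -> int:
    """Smallest number of pairs n >= 2 reaching the requested power.

    Inverts :func:`noncentral_t_power` by upward search; at the returned n
    the power is >= the target while at n - 1 it is below (or n == 2).
    """
    if spec is None:
        spec = PowerSpec(alpha=alpha, power=power, effect_size=effect_size,
                         tails=tails)
    for n in range(2, n_max + 1):
        if noncentral_t_power(n, spec.effect_size, spec.alpha, spec.tails) >= spec.power:
            return n
    raise ValueError(f"requested power not reachable with n <= {n_max}")


# --------------------------------------------------------------------------
# Subject-blocked two-way ANOVA (split-plot on cell means)
# --------------------------------------------------------------------------

@dataclass
class AnovaResult:
    """Sums-of-squares table of the subject-blocked two-way ANOVA."""

    table: pd.DataFrame           # rows: group, bin, group:bin, subject(group), residual
    design: str = "subject_blocked"
    alpha: float = DEFAULT_ALPHA

    def p(self, effect: str) -> float:
        return float(self.table.loc[effect, "p"])

    def F(self, effect: str) -> float:
        return float(self.table.loc[effect, "F"])

    def significant(self, effect: str) -> bool:
        return self.p(effect) <= self.alpha


def two_way_anova(data: pd.DataFrame, value: str = "width",
                  group: str = "group", bin_col: str = "bin",
                  subject: str = "subject",
                  alpha: float = DEFAULT_ALPHA) -> AnovaResult:
    """Subject-blocked two-way ANOVA of widths by group and angle bin.

    ``data`` holds one or more observations per (subject, bin); they are
    first reduced to cell means.  Every subject must belong to exactly one
    group and contribute every bin (bins missing from any subject are
    dropped).  Balanced designs reproduce the classical split-plot
    decomposition exactly; unbalanced group sizes use unweighted cell
    means with the harmonic group size.
    """
    df = data[[value, group, bin_col, subject]].dropna()
    if df[group].nunique() < 2:
        raise ValueError("need at least 2 groups")
    if df[bin_col].nunique() < 2:
        raise ValueError("need at least 2 angle bins")
    grp_of = df.groupby(subject)[group].nunique()
    if (grp_of > 1).any():
        raise ValueError("each subject must belong to exactly one group")

    cells = (df.groupby([group, subject, bin_col])[value].mean()
               .rename("y").reset_index())
    # keep only bins observed for every subject
    n_sub = cells[subject].nunique()
    bin_counts = cells.groupby(bin_col)[subject].nunique()
    common = bin_counts[bin_counts == n_sub].index
    cells = cells[cells[bin_col].isin(common)]
    if cells[bin_col].nunique() < 2:
        raise ValueError("fewer than 2 bins are shared by all subjects")
    sizes = cells.groupby(group)[subject].nunique()
    if (sizes < 2).any():
        raise ValueError("need at least 2 subjects per group")

    # cube y[g][s, b] per group
    groups = sorted(cells[group].unique())
    bins_ = np.sort(cells[bin_col].unique())
    B = len(bins_)
    per_group = []
    for g in groups:
        sub = cells[cells[group] == g].pivot(index=subject, columns=bin_col,
                                             values="y")
        sub = sub.reindex(columns=bins_)
        if sub.isna().any().any():
            raise ValueError("incomplete subject-by-bin table after cell averaging")
        per_group.append(sub.to_numpy())

    S_g = np.array([a.shape[0] for a in per_group])
    G = len(groups)
    n_tilde = G / np.sum(1.0 / S_g)          # harmonic mean group size
    balanced = np.all(S_g == S_g[0])
    w = S_g if balanced else np.full(G, n_tilde)

    mu_gb = np.stack([a.mean(axis=0) for a in per_group])   # (G, B) cell means
    mu_g = mu_gb.mean(axis=1)                               # (G,)
    mu_b = np.average(mu_gb, axis=0)                        # unweighted over groups
    mu = float(mu_gb.mean())

    ss_group = B * float(np.sum(w * (mu_g - mu) ** 2))
    ss_bin = float(np.sum(w)) * float(np.sum((mu_b - mu) ** 2))
    inter = mu_gb - mu_g[:, None] - mu_b[None, :] + mu
    ss_inter = float(np.sum(w[:, None] * inter ** 2))

    ss_subj = 0.0
    ss_resid = 0.0
    for gi, a in enumerate(per_group):
        subj_mean = a.mean(axis=1)                          # (S_g,)
        ss_subj += B * float(np.sum((subj_mean - subj_mean.mean()) ** 2))
        resid = a - subj_mean[:, None] - mu_gb[gi][None, :] + mu_gb[gi].mean()
        ss_resid += float(np.sum(resid ** 2))

    df_group = G - 1
    df_subj = int(np.sum(S_g)) - G
    df_bin = B - 1
    df_inter = (G - 1) * (B - 1)
    df_resid = df_subj * (B - 1)

    ms = lambda ss, d: ss / d if d > 0 else np.nan
    fstat = lambda num, den: (num / den if den > 0 else
                              (np.inf if num > 0 else np.nan))
    ms_subj, ms_resid = ms(ss_subj, df_subj), ms(ss_resid, df_resid)
    rows = {
        "group": (ss_group, df_group, fstat(ms(ss_group, df_group), ms_subj), df_subj),
        "bin": (ss_bin, df_bin, fstat(ms(ss_bin, df_bin), ms_resid), df_resid),
        "group:bin": (ss_inter, df_inter, fstat(ms(ss_inter, df_inter), ms_resid),
                      df_resid),
    }
    table = pd.DataFrame(
        [(e, ss, d, ms(ss, d), F, stats.f.sf(F, d, dfe), dfe)
         for e, (ss, d, F, dfe) in rows.items()],
        columns=["effect", "SS", "df", "MS", "F", "p", "df_error"],
    ).set_index("effect")
    table.loc["subject(group)"] = [ss_subj, df_subj, ms_subj, np.nan, np.nan, np.nan]
    table.loc["residual"] = [ss_resid, df_resid, ms_resid, np.nan, np.nan, np.nan]
    return AnovaResult(table=table, alpha=alpha)


# --------------------------------------------------------------------------
# Tukey HSD on cell means
# --------------------------------------------------------------------------

@dataclass
class TukeyResult:
    """Pairwise group contrasts with studentized-range adjusted p values."""

    table: pd.DataFrame           # group_a, group_b, diff, se, q, p_adj
    df_error: float
    k: int

    def p(self, a, b) -> float:
        t = self.table
        hit = t[((t.group_a == a) & (t.group_b == b))
                | ((t.group_a == b) & (t.group_b == a))]
        if hit.empty:
            raise KeyError(f"no contrast {a} vs {b}")
        return float(hit["p_adj"].iloc[0])


def tukey_hsd(means: dict, mse: float, df_error: float, n: dict | int) -> TukeyResult:
    """Tukey(-Kramer) HSD from group means, an ANOVA error mean square and
    its df.

    ``n`` is the per-group sample count (dict or common int).  For two
    groups the adjusted p equals the pooled two-sample t p exactly
    (q = t * sqrt(2)).  Adjusted p values are never below the unadjusted
    pairwise p.
    """
    if df_error < 1:
        raise ValueError("df_error must be >= 1")
    names = list(means)
    k = len(names)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if isinstance(n, int):
        n = {g: n for g in names}
    rows = []
    for a, b in itertools.combinations(names, 2):
        diff = float(means[a]) - float(means[b])
        se = np.sqrt(mse / 2.0 * (1.0 / n[a] + 1.0 / n[b]))  # Tukey-Kramer
        q = abs(diff) / se
        p = float(stats.studentized_range.sf(q, k, df_error))
        rows.append((a, b, diff, se * np.sqrt(2.0), q, min(max(p, 0.0), 1.0)))
    table = pd.DataFrame(rows, columns=["group_a", "group_b", "diff", "se",
                                        "q", "p_adj"])
    return TukeyResult(table=table, df_error=float(df_error), k=k)


def tukey_posthoc_by_bin(data: pd.DataFrame, value: str = "width",
                         group: str = "group", bin_col: str = "bin",
                         subject: str = "subject") -> pd.DataFrame:
    """All pairwise group contrasts within each angle bin.

    Per bin, group means are compared on subject means with the one-way
    between-subject error term, Tukey adjusted.  Returns a long table
    (bin, group_a, group_b, diff, p_adj).
    """
    out = []
    for b, chunk in data.groupby(bin_col):
        cell = chunk.groupby([group, subject])[value].mean().reset_index()
        sizes = cell.groupby(group)[subject].count()
        if (sizes < 2).any() or len(sizes) < 2:
            continue
        means = cell.groupby(group)[value].mean().to_dict()
        resid = cell[value] - cell[group].map(means)
        df_err = len(cell) - len(sizes)
        mse = float((resid ** 2).sum() / df_err)
        res = tukey_hsd(means, mse, df_err, sizes.to_dict())
        t = res.table.assign(**{bin_col: b})
        out.append(t[[bin_col, "group_a", "group_b", "diff", "p_adj"]])
    if not out:
        raise ValueError("no bin had >= 2 groups with >= 2 subjects")
    return pd.concat(out, ignore_index=True)
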