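"""Inferential machinery: split-plot ANOVA, Duncan post-hoc, correlations.

``rm_anova`` implements the classical univariate mixed (split-plot)
repeated-measures ANOVA in the general linear model: between-subject effects
are tested against the subjects-within-groups mean square, each within-subject
effect (and its interactions with the between factors) against its own
effect-by-subject mean square.  Sums of squares are Type III (sigma-restricted
sum-to-zero coding), so unbalanced between-subject cells are handled; the
within-subject design must be complete and balanced.  Covariates enter the
between-subject stratum only.

``duncan_posthoc`` is Duncan's multiple range test with studentized-range
critical values at protection level ``1 - (1 - alpha)^(p - 1)`` for a span of
``p`` ordered means.  ``compare_correlations_fisher`` implements the classical
two-sample z test on Fisher-transformed correlation coefficients with standard
error ``sqrt(1/(n1 - 3) + 1/(n2 - 3))``.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


# --------------------------------------------------------------------------
# repeated-measures ANOVA
# --------------------------------------------------------------------------
@dataclass
class AnovaSpec:
    """Model specification for :func:`rm_anova` on a tidy long table."""

    response: str
    between: list[str] = field(default_factory=list)
    within: list[str] = field(default_factory=list)
    covariates: list[str] = field(default_factory=list)
    subject_id: str = "subject"


def _sum_code(values: pd.Series, levels: list) -> np.ndarray:
    """Sum-to-zero (deviation) contrast columns for one factor."""
    k = len(levels)
    out = np.zeros((len(values), k - 1))
    idx = {lev: i for i, lev in enumerate(levels)}
    codes = values.map(idx).to_numpy()
    for j in range(k - 1):
        out[codes == j, j] = 1.0
    out[codes == k - 1, :] = -1.0
    return out


def _term_columns(
    data: pd.DataFrame, term: tuple[str, ...], levels: dict[str, list], covariates: list[str]
) -> np.ndarray:
    """Design columns for a term: product of factor contrasts / covariates."""
    blocks = []
    for name in term:
        if name in covariates:
            col = data[name].to_numpy(dtype=float)
            blocks.append((col - col.mean())[:, None])
        else:
            blocks.append(_sum_code(data[name], levels[name]))
    cols = blocks[0]
    for b in blocks[1:]:
        cols = np.einsum("ij,ik->ijk", cols, b).reshape(len(data), -1)
    return cols


def _sse(y: np.ndarray, x: np.ndarray) -> tuple[float, int]:
    beta, _, rank, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return float(resid @ resid), int(rank)


def _f_and_p(ss: float, df1: int, ms_err: float, df2: int, y_scale: float) -> tuple[float, float]:
    """F ratio with a guard for numerically zero strata (constant data)."""
    tiny = 1e-12 * (1.0 + y_scale)
    ms = ss / df1
    if ms_err <= tiny:
        f = 0.0 if ms <= tiny else np.inf
    else:
        f = ms / ms_err
    p = float(sps.f.sf(f, df1, df2)) if np.isfinite(f) else 0.0
    return float(f), p


def _interaction_terms(factors: list[str]) -> list[tuple[str, ...]]:
    terms = []
    for r in range(1, len(factors) + 1):
        terms.extend(itertools.combinations(factors, r))
    return terms


def _check_design(data: pd.DataFrame, spec: AnovaSpec) -> tuple[int, dict[str, list]]:
    levels = {f: sorted(data[f].unique().tolist()) for f in spec.between + spec.within}
    m = int(np.prod([len(levels[w]) for w in spec.within])) if spec.within else 1
    counts = data.groupby(spec.subject_id, sort=False).size()
    if not (counts == m).all():
        raise ValueError("within-subject design must be complete: every subject needs "
                         f"exactly {m} rows")
    if spec.within:
        cells = data.groupby([spec.subject_id] + spec.within, sort=False).size()
        if not (cells == 1).all():
            raise ValueError("each subject must have exactly one observation per within cell")
    per_subject = data.groupby(spec.subject_id, sort=False)[spec.between].nunique()
    if spec.between and (per_subject > 1).any().any():
        raise ValueError("each subject must belong to exactly one between-subject cell")
    if spec.between:
        cell_sizes = data.drop_duplicates(spec.subject_id).groupby(spec.between).size()
        if (cell_sizes < 2).any():
            raise ValueError("each between-subject cell needs at least 2 subjects")
        expected_cells = int(np.prod([len(levels[b]) for b in spec.between]))
        if len(cell_sizes) < expected_cells:
            raise ValueError("missing between-subject cells")
    return m, levels


def rm_anova(data: pd.DataFrame, spec: AnovaSpec) -> pd.DataFrame:
    """Mixed repeated-measures ANOVA with partitioned Type III sums of squares.

    Returns one row per effect with columns ``effect``, ``ss``, ``df1``,
    ``df2``, ``ms``, ``ms_error``, ``F``, ``p``, ``stratum``, plus one
    ``error(...)`` row per error stratum.  No sphericity correction is
    applied; the degrees of freedom are the uncorrected univariate ones.
    """
    data = data.reset_index(drop=True)
    m, levels = _check_design(data, spec)
    results: list[dict] = []

    # ---------------- between-subject stratum: subject means ----------------
    group_cols = [spec.subject_id] + spec.between + spec.covariates
    subj = data.groupby(group_cols, sort=False, as_index=False)[spec.response].mean()
    y_b = subj[spec.response].to_numpy(dtype=float)
    n_subj = len(subj)

    between_terms = _interaction_terms(spec.between)
    cov_terms = [(c,) for c in spec.covariates]
    all_b_terms = cov_terms + between_terms
    term_cols = {t: _term_columns(subj, t, levels, spec.covariates) for t in all_b_terms}

    x_full = np.column_stack([np.ones(n_subj)] + [term_cols[t] for t in all_b_terms]) \
        if all_b_terms else np.ones((n_subj, 1))
    sse_full, rank_full = _sse(y_b, x_full)
    df_err_b = n_subj - rank_full
    ms_err_b = sse_full * m / df_err_b
    for t in all_b_terms:
        others = [term_cols[u] for u in all_b_terms if u != t]
        x_red = np.column_stack([np.ones(n_subj)] + others) if others else np.ones((n_subj, 1))
        sse_red, _ = _sse(y_b, x_red)
        ss = max(sse_red - sse_full, 0.0) * m
        df1 = term_cols[t].shape[1]
        f, p = _f_and_p(ss, df1, ms_err_b, df_err_b, float(y_b @ y_b))
        results.append(
            {
                "effect": ":".join(t),
                "ss": ss,
                "df1": df1,
                "df2": df_err_b,
                "ms": ss / df1,
                "ms_error": ms_err_b,
                "F": f,
                "p": p,
                "stratum": "between",
            }
        )
    results.append(
        {
            "effect": "error(between)",
            "ss": sse_full * m,
            "df1": df_err_b,
            "df2": np.nan,
            "ms": ms_err_b,
            "ms_error": np.nan,
            "F": np.nan,
            "p": np.nan,
            "stratum": "between",
        }
    )

    # ------------- within-subject strata: one per within-effect -------------
    for omega in _interaction_terms(spec.within):
        other_within = [w for w in spec.within if w not in omega]
        scale = int(np.prod([len(levels[w]) for w in other_within])) if other_within else 1
        coll = data.groupby([spec.subject_id] + spec.between + list(omega),
                            sort=False, as_index=False)[spec.response].mean()
        y_w = coll[spec.response].to_numpy(dtype=float)
        n_rows = len(coll)

        subj_dummies = pd.get_dummies(coll[spec.subject_id], dtype=float).to_numpy()
        omega_cols = _term_columns(coll, omega, levels, spec.covariates)
        inter_terms = [omega + bt for bt in between_terms]
        inter_cols = {t: _term_columns(coll, t, levels, spec.covariates) for t in inter_terms}

        x_full = np.column_stack([subj_dummies, omega_cols] + list(inter_cols.values()))
        sse_full, rank_full = _sse(y_w, x_full)
        df_err = n_rows - rank_full
        ms_err = sse_full * scale / df_err

        stratum_name = ":".join(omega)
        targets: list[tuple[str, np.ndarray]] = [(stratum_name, omega_cols)]
        targets += [(":".join(t), inter_cols[t]) for t in inter_terms]
        for name, cols in targets:
            keep = [c for nm, c in targets if nm != name]
            x_red = np.column_stack([subj_dummies] + keep)
            sse_red, _ = _sse(y_w, x_red)
            ss = max(sse_red - sse_full, 0.0) * scale
            df1 = cols.shape[1]
            f, p = _f_and_p(ss, df1, ms_err, df_err, float(y_w @ y_w))
            results.append(
                {
                    "effect": name,
                    "ss": ss,
                    "df1": df1,
                    "df2": df_err,
                    "ms": ss / df1,
                    "ms_error": ms_err,
                    "F": f,
                    "p": p,
                    "stratum": stratum_name,
                }
            )
        results.append(
            {
                "effect": f"error({stratum_name})",
                "ss": sse_full * scale,
                "df1": df_err,
                "df2": np.nan,
                "ms": ms_err,
                "ms_error": np.nan,
                "F": np.nan,
                "p": np.nan,
                "stratum": stratum_name,
            }
        )
    return pd.DataFrame(results)


# --------------------------------------------------------------------------
# Duncan's multiple range test
# --------------------------------------------------------------------------
def duncan_posthoc(
    cell_means: pd.Series | dict,
    cell_ns: pd.Series | dict,
    ms_error: float,
    df_error: float,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Duncan's multiple range test over a set of cell means.

    A pair of means spanning ``p`` ranks in the ordered sequence is declared
    significant iff its absolute difference exceeds
    ``q(1 - (1-alpha)^(p-1); p, df) * sqrt(ms_error / n_h)`` — ``n_h`` the
    harmonic mean of the two cell sizes — *and* every enclosing range is
    itself significant (multiple-range protection).

    Returns one row per pair: ``level_a``, ``level_b`` (a has the smaller
    mean), ``diff``, ``span``, ``critical``, ``significant``.
    """
    means = pd.Series(cell_means, dtype=float)
    ns = pd.Series(cell_ns, dtype=float).reindex(means.index)
    if ms_error <= 0:
        raise ValueError("ms_error must be positive")
    if len(means) < 2:
        raise ValueError("need at least 2 cells")
    order = means.sort_values().index.to_list()
    k = len(order)
    records = {}
    blocked: list[tuple[int, int]] = []  # windows declared non-significant
    for span in range(k, 1, -1):
        protection = (1.0 - alpha) ** (span - 1)
        for i in range(0, k - span + 1):
            j = i + span - 1
            a, b = order[i], order[j]
            nh = 2.0 / (1.0 / ns[a] + 1.0 / ns[b])
            q_crit = sps.studentized_range.ppf(protection, span, df_error)
            critical = q_crit * np.sqrt(ms_error / nh)
            diff = means[b] - means[a]
            inside_blocked = any(bi <= i and j <= bj for bi, bj in blocked)
            significant = bool(diff > critical) and not inside_blocked
            if not significant:
                blocked.append((i, j))
            records[(a, b)] = {
                "level_a": a,
                "level_b": b,
                "diff": float(diff),
                "span": span,
                "critical": float(critical),
                "significant": significant,
            }
    return pd.DataFrame(list(records.values()))


# --------------------------------------------------------------------------
# correlation tests
# --------------------------------------------------------------------------
def pvalue_from_r(r: float, n: int) -> float:
    """Two-sided p for a correlation via ``t = r sqrt(n-2)/sqrt(1-r^2)``."""
    if n < 4:
        raise ValueError("need n >= 4")
    if abs(r) >= 1:
        return 0.0
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    return float(2.0 * sps.t.sf(abs(t), n - 2))


@dataclass
class CorrResult:
    r: float
    p: float
    n: int
    method: str


def corr_test(
    x: np.ndarray,
    y: np.ndarray,
    method: str = "auto",
    normality_alpha: float = 0.05,
) -> CorrResult:
    """Pearson or Spearman correlation with a t-based two-sided p-value.

    ``method='auto'`` applies a Shapiro-Wilk normality gate to both samples:
    Pearson when neither rejects normality at ``normality_alpha``, Spearman
    otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 4:
        raise ValueError("x and y must have equal length >= 4")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance input")
    if method == "auto":
        normal = all(sps.shapiro(v).pvalue > normality_alpha for v in (x, y))
        method = "pearson" if normal else "spearman"
    if method == "pearson":
        r = float(np.corrcoef(x, y)[0, 1])
    elif method == "spearman":
        r = float(sps.spearmanr(x, y).statistic)
    else:
        raise ValueError(f"unknown method {method!r}")
    return CorrResult(r=r, p=pvalue_from_r(r, x.size), n=int(x.size), method=method)


def compare_correlations_fisher(
    r1: float, n1: int, r2: float, n2: int, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Fisher r-to-z comparison of two independent correlations.

    ``z = (atanh r1 - atanh r2) / sqrt(1/(n1-3) + 1/(n2-3))``; p from the
    standard normal.  ``alternative``: 'two-sided', 'less' (H1: rho1 < rho2)
    or 'greater' (H1: rho1 > rho2).
    """
    if n1 <= 3 or n2 <= 3:
        raise ValueError("need n > 3 in both samples")
    if abs(r1) >= 1 or abs(r2) >= 1:
        raise ValueError("|r| must be < 1")
    z = (np.arctanh(r1) - np.arctanh(r2)) / np.sqrt(1.0 / (n1 - 3) + 1.0 / (n2 - 3))
    if alternative == "two-sided":
        p = 2.0 * sps.norm.sf(abs(z))
    elif alternative == "less":
        p = sps.norm.cdf(z)
    elif alternative == "greater":
        p = sps.norm.sf(z)
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return float(z), float(p)


# --------------------------------------------------------------------------
# edge-wise group contrasts with FDR
# --------------------------------------------------------------------------
def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    if p.size == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


def edge_group_compare(
    z_by_subject: dict[str, pd.DataFrame],
    groups: dict[str, str] | pd.Series,
    group_a: str,
    group_b: str,
) -> pd.DataFrame:
    """Edge-wise two-sample GLM contrast of Fisher-z connectivity.

    For each ROI pair: ``beta`` = mean z in ``group_a`` minus mean z in
    ``group_b``; ``T`` and ``p_unc`` from the pooled-variance two-sample
    t-test; ``p_fdr`` by Benjamini-Hochberg across all edges.  One-sample
    within-group tests of mean z against zero are emitted alongside
    (``mean_a``, ``t_a``, ``p_a``, ``p_a_fdr`` and likewise for b).
    Rows are sorted by ``p_unc``.
    """
    groups = pd.Series(dict(groups) if not isinstance(groups, pd.Series) else groups)
    subj_a = [s for s in z_by_subject if groups.get(s) == group_a]
    subj_b = [s for s in z_by_subject if groups.get(s) == group_b]
    if len(subj_a) < 2 or len(subj_b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    ref = z_by_subject[subj_a[0]]
    labels = list(ref.columns)
    for s, zmat in z_by_subject.items():
        if list(zmat.columns) != labels:
            raise ValueError(f"subject {s} has a different ROI set")

    def stack(subjects: list[str]) -> np.ndarray:
        return np.stack([z_by_subject[s].to_numpy() for s in subjects])

    za, zb = stack(subj_a), stack(subj_b)
    iu = np.triu_indices(len(labels), k=1)
    ea, eb = za[:, iu[0], iu[1]], zb[:, iu[0], iu[1]]  # subjects x edges

    t_ab, p_ab = sps.ttest_ind(ea, eb, axis=0, equal_var=True)
    t_a, p_a = sps.ttest_1samp(ea, 0.0, axis=0)
    t_b, p_b = sps.ttest_1samp(eb, 0.0, axis=0)

    out = pd.DataFrame(
        {
            "roi_i": [labels[i] for i in iu[0]],
            "roi_j": [labels[j] for j in iu[1]],
            "beta": ea.mean(axis=0) - eb.mean(axis=0),
            "T": t_ab,
            "p_unc": p_ab,
            "p_fdr": bh_fdr(p_ab),
            "mean_a": ea.mean(axis=0),
            "t_a": t_a,
            "p_a": p_a,
            "p_a_fdr": bh_fdr(p_a),
            "mean_b": eb.mean(axis=0),
            "t_b": t_b,
            "p_b": p_b,
            "p_b_fdr": bh_fdr(p_b),
        }
    )
    out.attrs["group_a"], out.attrs["group_b"] = group_a, group_b
    out.attrs["n_a"], out.attrs["n_b"] = len(subj_a), len(subj_b)
    return out.sort_values("p_unc", kind="mergesort").reset_index(drop=True)
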