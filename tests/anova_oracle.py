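"""Independent split-plot ANOVA oracle for balanced 2x2-between designs.

Computes every sum of squares from marginal cell means with the classical
closed-form formulas (no design matrices, no regression), so it shares no
code path with the package implementation it cross-checks.  Valid only for
balanced data: equal subjects per between cell, one observation per subject
per within level.
"""

import numpy as np
import pandas as pd
from scipy import stats as sps


def split_plot_oracle(data: pd.DataFrame, a_col: str, b_col: str, w_col: str,
                      subject: str = "subject", value: str = "value") -> pd.DataFrame:
    df = data.copy()
    a_levels = sorted(df[a_col].unique())
    b_levels = sorted(df[b_col].unique())
    w_levels = sorted(df[w_col].unique())
    assert len(a_levels) == 2 and len(b_levels) == 2
    w = len(w_levels)
    subjects = df[subject].unique()
    n_subj = len(subjects)
    n_cell = n_subj // 4  # subjects per between cell (balanced)

    grand = df[value].mean()
    m_a = df.groupby(a_col)[value].mean()
    m_b = df.groupby(b_col)[value].mean()
    m_ab = df.groupby([a_col, b_col])[value].mean()
    m_w = df.groupby(w_col)[value].mean()
    m_aw = df.groupby([a_col, w_col])[value].mean()
    m_bw = df.groupby([b_col, w_col])[value].mean()
    m_abw = df.groupby([a_col, b_col, w_col])[value].mean()
    m_subj = df.groupby(subject)[value].mean()

    ss_a = w * 2 * n_cell * sum((m_a[a] - grand) ** 2 for a in a_levels)
    ss_b = w * 2 * n_cell * sum((m_b[b] - grand) ** 2 for b in b_levels)
    ss_ab = w * n_cell * sum(
        (m_ab[a, b] - m_a[a] - m_b[b] + grand) ** 2 for a in a_levels for b in b_levels
    )
    ss_between_total = w * sum((m_subj[s] - grand) ** 2 for s in subjects)
    ss_subj_within = ss_between_total - ss_a - ss_b - ss_ab

    ss_w = 4 * n_cell * sum((m_w[v] - grand) ** 2 for v in w_levels)
    ss_wa = 2 * n_cell * sum(
        (m_aw[a, v] - m_a[a] - m_w[v] + grand) ** 2 for a in a_levels for v in w_levels
    )
    ss_wb = 2 * n_cell * sum(
        (m_bw[b, v] - m_b[b] - m_w[v] + grand) ** 2 for b in b_levels for v in w_levels
    )
    ss_wab = n_cell * sum(
        (m_abw[a, b, v] - m_ab[a, b] - m_aw[a, v] - m_bw[b, v]
         + m_a[a] + m_b[b] + m_w[v] - grand) ** 2
        for a in a_levels for b in b_levels for v in w_levels
    )

    # W x subject residual, computed observation-wise
    cell_of = df.drop_duplicates(subject).set_index(subject)[[a_col, b_col]]
    resid_sq = 0.0
    for row in df.itertuples(index=False):
        rec = row._asdict()
        a, b, v, s = rec[a_col], rec[b_col], rec[w_col], rec[subject]
        resid = rec[value] - m_subj[s] - m_abw[a, b, v] + m_ab[a, b]
        resid_sq += resid**2
    ss_w_err = resid_sq

    df_subj = n_subj - 4
    df_w_err = (w - 1) * (n_subj - 4)
    ms_subj = ss_subj_within / df_subj
    ms_w_err = ss_w_err / df_w_err

    rows = []
    for name, ss, df1, ms_e, df2 in [
        (a_col, ss_a, 1, ms_subj, df_subj),
        (b_col, ss_b, 1, ms_subj, df_subj),
        (f"{a_col}:{b_col}", ss_ab, 1, ms_subj, df_subj),
        (w_col, ss_w, w - 1, ms_w_err, df_w_err),
        (f"{w_col}:{a_col}", ss_wa, w - 1, ms_w_err, df_w_err),
        (f"{w_col}:{b_col}", ss_wb, w - 1, ms_w_err, df_w_err),
        (f"{w_col}:{a_col}:{b_col}", ss_wab, (w - 1), ms_w_err, df_w_err),
    ]:
        f_stat = (ss / df1) / ms_e
        rows.append({"effect": name, "ss": ss, "df1": df1, "df2": df2,
                     "F": f_stat, "p": float(sps.f.sf(f_stat, df1, df2))})
    return pd.DataFrame(rows)
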