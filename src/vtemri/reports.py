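"""Report tables for a cohort validation study.

Four tables mirror the layout of a method-validation report:

1. demographics per group with between-group tests and a multivariable
   regression of aT2* on weight, height and BMI;
2. aT2* and CSA compared by side, sex and age group;
3. reader agreement: per-reader aT2* by side, between-reader MSE, Dice and
   ICC summaries;
4. SNR and CNR per echo and side with echo and side comparisons.

All aT2* values are in ms, CSA in mm^2; report cells round to 2 decimals
while the underlying computations run at full precision.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import stats as vstats


def _msd(values) -> tuple[float, float]:
    v = np.asarray(values, dtype=float)
    return float(v.mean()), float(v.std(ddof=1)) if v.size > 1 else 0.0


def demographics_table(cohort: pd.DataFrame, at2_by_subject: pd.Series,
                       alpha: float = 0.05, family: int = 6) -> pd.DataFrame:
    """Group demographics with young-vs-senior t tests and the regression
    of per-subject aT2* on weight, height and BMI."""
    young = cohort[cohort.group == "young"]
    senior = cohort[cohort.group == "senior"]
    reg = vstats.multivariable_regression(
        at2_by_subject.loc[cohort.subject_id].to_numpy(),
        cohort[["weight_kg", "height_m", "bmi"]].set_axis(cohort.subject_id))
    rows = []
    rows.append({
        "parameter": "sex (M/F)",
        "young": f"{(young.sex == 'M').sum()} / {(young.sex == 'F').sum()}",
        "senior": f"{(senior.sex == 'M').sum()} / {(senior.sex == 'F').sum()}",
        "p_t_test": np.nan, "regression_se": np.nan, "regression_p": np.nan})
    for label, col, term in (("age (years)", "age", None),
                             ("body weight (kg)", "weight_kg", "weight_kg"),
                             ("height (m)", "height_m", "height_m"),
                             ("BMI (kg/m^2)", "bmi", "bmi")):
        t = vstats.two_sample_t(young[col], senior[col])
        my, sy = _msd(young[col])
        ms, ss = _msd(senior[col])
        rows.append({
            "parameter": label,
            "young": f"{my:.2f} ± {sy:.2f}",
            "senior": f"{ms:.2f} ± {ss:.2f}",
            "p_t_test": round(t.p, 4),
            "regression_se": round(float(reg.table.loc[term, "se"]), 2) if term else np.nan,
            "regression_p": round(float(reg.table.loc[term, "p"]), 3) if term else np.nan})
    out = pd.DataFrame(rows)
    out.attrs["alpha_adjusted"] = vstats.bonferroni_threshold(alpha, family).rounded
    out.attrs["regression_condition_number"] = reg.condition_number
    return out


def group_comparison_table(summaries: pd.DataFrame, cohort: pd.DataFrame,
                           alpha: float = 0.05, family: int = 6) -> pd.DataFrame:
    """aT2* and CSA by side, sex and age group.

    ``summaries`` needs columns subject_id, side, at2_ms, csa_mm2 (one row
    per subject x side). Side comparisons are paired across subjects and
    routed through a Shapiro-Wilk normality gate (paired t vs Wilcoxon);
    sex and age-group comparisons pool per-side observations and use a
    two-sample t test.
    """
    df = summaries.merge(cohort[["subject_id", "sex", "group"]], on="subject_id")
    wide_at2 = df.pivot(index="subject_id", columns="side", values="at2_ms")
    wide_csa = df.pivot(index="subject_id", columns="side", values="csa_mm2")

    def row(name, at2_vals, csa_vals, p_at2, p_csa):
        m, s = _msd(at2_vals)
        mc, sc = _msd(csa_vals)
        return {"group": name, "n": len(at2_vals),
                "at2_ms": round(m, 2), "at2_sd": round(s, 2),
                "p_at2": round(p_at2, 3) if np.isfinite(p_at2) else np.nan,
                "csa_mm2": round(mc, 1), "csa_sd": round(sc, 1),
                "p_csa": round(p_csa, 3) if np.isfinite(p_csa) else np.nan}

    rows = []
    p_side_at2 = vstats.compare_paired(wide_at2["right"], wide_at2["left"]).p
    p_side_csa = vstats.compare_paired(wide_csa["right"], wide_csa["left"]).p
    rows.append(row("right", df[df.side == "right"].at2_ms,
                    df[df.side == "right"].csa_mm2, p_side_at2, p_side_csa))
    rows.append(row("left", df[df.side == "left"].at2_ms,
                    df[df.side == "left"].csa_mm2, np.nan, np.nan))
    for col, levels in (("sex", ("M", "F")), ("group", ("young", "senior"))):
        a = df[df[col] == levels[0]]
        b = df[df[col] == levels[1]]
        p_at2 = vstats.two_sample_t(a.at2_ms, b.at2_ms).p
        p_csa = vstats.two_sample_t(a.csa_mm2, b.csa_mm2).p
        names = {"M": "male", "F": "female"}.get(levels[0], levels[0]), \
            {"M": "male", "F": "female"}.get(levels[1], levels[1])
        rows.append(row(names[0], a.at2_ms, a.csa_mm2, p_at2, p_csa))
        rows.append(row(names[1], b.at2_ms, b.csa_mm2, np.nan, np.nan))
    out = pd.DataFrame(rows)
    out.attrs["alpha_adjusted"] = vstats.bonferroni_threshold(alpha, family).rounded
    out.attrs["total_observations"] = int(len(df))
    return out


@dataclass
class AgreementInputs:
    """Per-side reader measurements for the agreement table.

    ``at2`` maps reader name -> DataFrame indexed by subject with columns
    right/left (ms); ``dice`` maps comparison name -> DataFrame with the
    same shape holding per-subject Dice values.
    """

    at2: dict[str, pd.DataFrame]
    dice: dict[str, pd.DataFrame]
    intra_at2: dict[str, pd.DataFrame] | None = None   # timepoint -> table


def agreement_table(inputs: AgreementInputs,
                    icc_form: str = "twoway_agreement") -> pd.DataFrame:
    """Reader agreement summary: per-reader means, MSE, Dice and ICC.

    MSE is the mean squared difference between the two readers' per-subject
    aT2* values, per side.
    """
    readers = list(inputs.at2.keys())
    rows = []
    for reader in readers:
        tab = inputs.at2[reader]
        m_r, s_r = _msd(tab["right"])
        m_l, s_l = _msd(tab["left"])
        p_side = vstats.compare_paired(tab["right"], tab["left"]).p
        rows.append({"measure": f"aT2* {reader}",
                     "right": f"{m_r:.2f} ± {s_r:.2f}",
                     "left": f"{m_l:.2f} ± {s_l:.2f}",
                     "p_value": round(p_side, 3)})
    if len(readers) == 2:
        a, b = (inputs.at2[r] for r in readers)
        for side in ("right", "left"):
            mse = float(((a[side] - b[side]) ** 2).mean())
            rows.append({"measure": f"MSE between readers ({side})",
                         "right": round(mse, 3) if side == "right" else "",
                         "left": round(mse, 3) if side == "left" else "",
                         "p_value": np.nan})
    for name, tab in inputs.dice.items():
        m_r, s_r = _msd(tab["right"])
        m_l, s_l = _msd(tab["left"])
        rows.append({"measure": f"Dice ({name})",
                     "right": f"{m_r:.2f} ± {s_r:.2f}",
                     "left": f"{m_l:.2f} ± {s_l:.2f}", "p_value": np.nan})
    if len(readers) == 2:
        a, b = (inputs.at2[r] for r in readers)
        for side in ("right", "left"):
            res = vstats.icc(np.column_stack([a[side], b[side]]), form=icc_form)
            rows.append({"measure": f"ICC (inter-reader, {side})",
                         "right": round(res.value, 3) if side == "right" else "",
                         "left": round(res.value, 3) if side == "left" else "",
                         "p_value": round(res.p, 4)})
    if inputs.intra_at2:
        tps = list(inputs.intra_at2.keys())
        if len(tps) == 2:
            a, b = (inputs.intra_at2[t] for t in tps)
            for side in ("right", "left"):
                res = vstats.icc(np.column_stack([a[side], b[side]]), form=icc_form)
                rows.append({"measure": f"ICC (intra-reader, {side})",
                             "right": round(res.value, 3) if side == "right" else "",
                             "left": round(res.value, 3) if side == "left" else "",
                             "p_value": round(res.p, 4)})
    return pd.DataFrame(rows)


def snr_cnr_table(measures: pd.DataFrame) -> pd.DataFrame:
    """SNR/CNR summary per (echo, side) with echo and side comparisons.

    ``measures`` needs columns subject_id, side, echo (1 or 2), snr, cnr
    (one row per subject x side x echo).
    """
    rows = []
    for echo in (1, 2):
        for side in ("right", "left"):
            sel = measures[(measures.echo == echo) & (measures.side == side)]
            ms, ss = _msd(sel.snr)
            mc, sc = _msd(sel.cnr)
            rows.append({"image_set": f"Echo {echo} {side}",
                         "snr": round(ms, 2), "snr_sd": round(ss, 2),
                         "cnr": round(mc, 2), "cnr_sd": round(sc, 2)})
    wide = measures.pivot_table(index=["subject_id", "side"], columns="echo",
                                values=["snr", "cnr"])
    p_echo_snr = vstats.compare_paired(wide[("snr", 1)], wide[("snr", 2)]).p
    p_echo_cnr = vstats.compare_paired(wide[("cnr", 1)], wide[("cnr", 2)]).p
    ws = measures.pivot_table(index=["subject_id", "echo"], columns="side",
                              values=["snr", "cnr"])
    p_side_snr = vstats.compare_paired(ws[("snr", "right")], ws[("snr", "left")]).p
    p_side_cnr = vstats.compare_paired(ws[("cnr", "right")], ws[("cnr", "left")]).p
    rows.append({"image_set": "Echo 1 vs Echo 2 (p)",
                 "snr": round(p_echo_snr, 3), "snr_sd": np.nan,
                 "cnr": round(p_echo_cnr, 3), "cnr_sd": np.nan})
    rows.append({"image_set": "Right vs Left (p)",
                 "snr": round(p_side_snr, 3), "snr_sd": np.nan,
                 "cnr": round(p_side_cnr, 3), "cnr_sd": np.nan})
    return pd.DataFrame(rows)
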