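"""Covariate harmonisation and imputation for the survey panel.

The covariate panel is long format: one row per participant per wave with
sociodemographic and lifestyle covariates.  Medication use was collected
with different instruments across waves (a count of medicine types, a
yes/no item, or a mark-all-that-apply list) and is harmonised to binary.
Education was only measured at S1 and S6, so S3-S5 borrow from S1 and
S7-S8 from S6, with cross-fallback when the primary anchor is missing.
Remaining item missingness at S4-S7 borrows from the nearest subsequent
observed wave, and S8 from the preceding wave; a ``conventional`` switch
instead carries the last observed prior response forward at every wave.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .records import ConfigurationError

WAVES = tuple(range(1, 9))

CATEGORIES = {
    "area": ("urban", "inner_regional", "outer_regional_rural"),
    "marital": ("not_married", "married_defacto", "sep_div_wid"),
    "education": ("none", "school_certificate", "apprenticeship_diploma", "university"),
    "occupation": ("no_paid_job", "paid_job"),
    "income_manage": ("easy_not_bad", "difficult"),
    "smoking": ("never", "past", "current"),
    "physical_activity": ("nil_sedentary", "low", "moderate", "high"),
    "prescribed_med": ("no", "yes"),
    "otc_med": ("no", "yes"),
}

COVARIATE_COLUMNS = ("age",) + tuple(CATEGORIES)

#: MET.min/week band edges for the four physical-activity categories
MET_BANDS = (40.0, 600.0, 1200.0)


def categorize_physical_activity(met_min_per_week) -> np.ndarray:
    """Map MET.min/week to the four activity bands: nil/sedentary (0-39),
    low (40-599), moderate (600-1199), high (>=1200)."""
    met = np.asarray(met_min_per_week, dtype=float)
    labels = np.array(CATEGORIES["physical_activity"], dtype=object)
    return labels[np.searchsorted(MET_BANDS, met, side="right")]


def harmonize_medication(raw: pd.Series, encoding: str) -> pd.Series:
    """Reduce a wave's medication responses to no/yes.

    ``encoding`` tags the instrument: ``count`` (number of medicine types,
    >0 means yes), ``multiple`` (mark-all-that-apply; any mark means yes),
    or ``binary`` (already no/yes, passed through).  Missing stays missing.
    """
    if encoding == "binary":
        bad = raw.dropna()[~raw.dropna().isin(["no", "yes"])]
        if len(bad):
            raise ConfigurationError(f"binary medication values outside no/yes: {set(bad)}")
        return raw
    if encoding == "count":
        return raw.map(lambda v: v if pd.isna(v) else ("yes" if float(v) > 0 else "no"))
    if encoding == "multiple":
        def _any_marked(v):
            if isinstance(v, float) and np.isnan(v):
                return np.nan
            if isinstance(v, (list, tuple, set)):
                return "yes" if len(v) > 0 else "no"
            return "yes" if str(v).strip() else "no"
        return raw.map(_any_marked)
    raise ConfigurationError(f"unknown medication encoding {encoding!r}")


def _pivot(panel: pd.DataFrame, column: str) -> pd.DataFrame:
    wide = panel.pivot(index="participant_id", columns="wave", values=column)
    return wide.reindex(columns=list(WAVES))


def _unpivot_into(panel: pd.DataFrame, column: str, wide: pd.DataFrame) -> pd.DataFrame:
    long = wide.stack(future_stack=True).rename(column).reset_index()
    panel = panel.drop(columns=[column]).merge(long, on=["participant_id", "wave"], how="left")
    return panel


def impute_education(panel: pd.DataFrame) -> pd.DataFrame:
    """Fill education at S3-S5 from the S1 value (falling back to S6) and
    at S7-S8 from S6 (falling back to S1); S1/S6 observed values and rows
    missing both anchors are left as they are."""
    wide = _pivot(panel, "education")
    e1 = wide[1]
    e6 = wide[6]
    early = e1.fillna(e6)
    late = e6.fillna(e1)
    for w in (3, 4, 5):
        wide[w] = wide[w].fillna(early)
    for w in (7, 8):
        wide[w] = wide[w].fillna(late)
    return _unpivot_into(panel, "education", wide)


def fill_missing_covariates(
    panel: pd.DataFrame, direction: str = "as-stated"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Fill item missingness at S4-S8; returns (panel, fill log).

    ``as-stated``: waves S4-S7 borrow from the nearest subsequent observed
    wave and S8 from the preceding wave.  ``conventional``: every wave
    S4-S8 carries the last observed prior response forward.  Education is
    never touched here (see :func:`impute_education`); observed values are
    never changed, and values with no donor stay missing (logged).  The
    operation is idempotent.
    """
    if direction not in ("as-stated", "conventional"):
        raise ConfigurationError(f"unknown fill direction {direction!r}")
    log_rows = []
    out = panel.copy()
    for column in COVARIATE_COLUMNS:
        if column == "education" or column not in out.columns:
            continue
        wide = _pivot(out, column)
        before = wide.copy()
        with pd.option_context("future.no_silent_downcasting", True):
            if direction == "as-stated":
                filled = wide[[4, 5, 6, 7, 8]].bfill(axis=1)
                for w in (4, 5, 6, 7):
                    wide[w] = filled[w]
                wide[8] = wide[8].fillna(wide[7])
            else:
                filled = wide[list(WAVES)].ffill(axis=1)
                for w in (4, 5, 6, 7, 8):
                    wide[w] = filled[w]
        changed = wide.notna() & before.isna()
        for w in (4, 5, 6, 7, 8):
            for pid in wide.index[changed[w]]:
                log_rows.append({"participant_id": pid, "wave": w, "column": column})
        still_missing = wide.isna() & before.isna()
        for w in (4, 5, 6, 7, 8):
            for pid in wide.index[still_missing[w]]:
                log_rows.append(
                    {"participant_id": pid, "wave": w, "column": column, "unfilled": True}
                )
        out = _unpivot_into(out, column, wide)
    log = pd.DataFrame(log_rows, columns=["participant_id", "wave", "column", "unfilled"])
    if len(log):
        log["unfilled"] = log["unfilled"].map(lambda v: bool(v) if v is True else False)
    return out, log
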