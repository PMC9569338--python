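"""Kinetic slope fitting, QC filtering, and normalized signal matrices.

Each (peptide, group, chip) well contributes a series of intensities across
camera exposure times; the working signal is the OLS slope of intensity on
exposure time (scaled by a convention factor), with the fit's R^2 serving as
the linearity diagnostic for QC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from kinoscope.errors import ValidationError

SAMPLE_KEYS = ["group", "chip"]
WELL_KEYS = ["peptide_id", "group", "chip"]

QC_LOW_SIGNAL = "low_signal"
QC_NONLINEAR = "nonlinear"


def fit_slopes(series: pd.DataFrame, scale: float = 100.0) -> pd.DataFrame:
    """Fit intensity ~ exposure_ms by ordinary least squares per well.

    Returns one row per (peptide_id, group, chip) with columns:

    - ``slope``, ``intercept``, ``r_squared`` — raw OLS fit; a constant-
      intensity well has an undefined R^2, recorded as 0 with
      ``fit_flag == "constant"``.
    - ``signal`` — working signal: the slope floored at 0 and multiplied by
      ``scale`` (phosphorylation signal cannot be negative).
    - ``signal_at_max_exposure`` — intensity at the well's largest exposure,
      used by the low-signal QC rule.
    """
    df = series.copy()
    df["chip"] = df["chip"].astype(str)
    counts = df.groupby(WELL_KEYS)["exposure_ms"].nunique()
    thin = counts[counts < 2]
    if len(thin):
        raise ValidationError(
            f"wells with < 2 distinct exposures: {list(thin.index[:5])}"
        )

    x = df["exposure_ms"].to_numpy(dtype=float)
    y = df["intensity"].to_numpy(dtype=float)
    df = df.assign(_x=x, _y=y, _xx=x * x, _xy=x * y, _yy=y * y, _n=1.0)
    agg = df.groupby(WELL_KEYS, sort=True)[["_x", "_y", "_xx", "_xy", "_yy", "_n"]].sum()
    n = agg["_n"]
    sxx = agg["_xx"] - agg["_x"] ** 2 / n
    syy = agg["_yy"] - agg["_y"] ** 2 / n
    sxy = agg["_xy"] - agg["_x"] * agg["_y"] / n

    slope = sxy / sxx
    intercept = (agg["_y"] - slope * agg["_x"]) / n
    with np.errstate(invalid="ignore", divide="ignore"):
        r2 = np.where(syy > 0, (sxy**2) / (sxx * syy), 0.0)
    r2 = np.clip(r2, 0.0, 1.0)

    out = pd.DataFrame(
        {
            "slope": slope,
            "intercept": intercept,
            "r_squared": r2,
            "fit_flag": np.where(syy > 0, "", "constant"),
        },
        index=agg.index,
    )

    # intensity observed at each well's maximum exposure
    imax = df.groupby(WELL_KEYS, sort=True)["exposure_ms"].idxmax()
    out["signal_at_max_exposure"] = df.loc[imax.to_numpy(), "intensity"].to_numpy()
    out["signal"] = np.clip(out["slope"], 0.0, None) * scale
    return out.reset_index()


@dataclass
class QCResult:
    """Per-well QC flags plus the peptide keep-list for a comparison."""

    flags: pd.DataFrame  # per-well: qc_pass, qc_reasons
    keep: list[str]
    reasons: pd.DataFrame  # per excluded peptide: semicolon-joined reason codes
    low_signal_threshold: float
    linearity_threshold: float
    scope: str


def apply_qc(
    slopes: pd.DataFrame,
    low_signal_threshold: float = 2.0,
    linearity_threshold: float = 0.9,
    scope: str = "all",
    groups: list[str] | None = None,
) -> QCResult:
    """Flag wells and build the peptide keep-list.

    A well passes iff its intensity at the largest exposure is >=
    ``low_signal_threshold`` and its fit R^2 is >= ``linearity_threshold``.
    With ``scope="all"`` (default) a peptide is kept iff it passes in every
    sample of the comparison; ``scope="any"`` keeps it if it passes anywhere.
    ``groups`` restricts the comparison to a subset of group labels.
    """
    if low_signal_threshold < 0 or linearity_threshold < 0:
        raise ValidationError("QC thresholds must be >= 0")
    if scope not in ("all", "any"):
        raise ValidationError(f"scope must be 'all' or 'any', got {scope!r}")
    flags = slopes.copy()
    if groups is not None:
        flags = flags[flags["group"].isin(groups)].copy()
        if flags.empty:
            raise ValidationError(f"no samples for groups {groups}")
    low = flags["signal_at_max_exposure"] < low_signal_threshold
    nonlin = flags["r_squared"] < linearity_threshold
    flags["qc_pass"] = ~(low | nonlin)
    flags["qc_reasons"] = [
        ";".join(r for r, hit in ((QC_LOW_SIGNAL, lo), (QC_NONLINEAR, nl)) if hit)
        for lo, nl in zip(low, nonlin)
    ]

    agg = flags.groupby("peptide_id")["qc_pass"]
    kept_mask = agg.all() if scope == "all" else agg.any()
    keep = sorted(kept_mask.index[kept_mask])

    excluded = flags[~flags["peptide_id"].isin(keep)]
    reasons = (
        excluded[excluded["qc_reasons"] != ""]
        .groupby("peptide_id")["qc_reasons"]
        .apply(lambda s: ";".join(sorted(set(r for joined in s for r in joined.split(";")))))
        .reset_index()
    )
    return QCResult(
        flags=flags,
        keep=keep,
        reasons=reasons,
        low_signal_threshold=low_signal_threshold,
        linearity_threshold=linearity_threshold,
        scope=scope,
    )


@dataclass
class SignalMatrix:
    """Peptides x samples matrices of log2 signal and per-peptide Z scores.

    Columns are a (group, chip) MultiIndex; rows are peptide ids. ``zscore``
    rows have mean 0 and sample sd 1, except zero-variance rows, which are 0.
    """

    log2: pd.DataFrame
    zscore: pd.DataFrame
    floor: float

    @property
    def peptides(self) -> list[str]:
        return list(self.log2.index)

    def to_table(self, which: str = "log2") -> pd.DataFrame:
        mat = getattr(self, which)
        flat = mat.copy()
        flat.columns = [f"{g}:{c}" for g, c in mat.columns]
        return flat.reset_index()


def build_signal_matrix(
    slopes: pd.DataFrame,
    keep: list[str] | None = None,
    floor: float = 1.0,
    endpoint: bool = False,
) -> SignalMatrix:
    """Pivot working signals into a peptides x samples log2 matrix plus a
    per-peptide Z-scaled copy.

    Signals are floored at ``floor`` before log2 so zero-slope wells do not
    produce -inf. ``endpoint=True`` uses the max-exposure intensity instead of
    the fitted slope signal.
    """
    df = slopes
    if keep is not None:
        if not len(keep):
            raise ValidationError("empty peptide keep-list")
        df = df[df["peptide_id"].isin(keep)]
        if df.empty:
            raise ValidationError("keep-list matches no peptides in slopes")
    value = "signal_at_max_exposure" if endpoint else "signal"
    wide = df.pivot_table(index="peptide_id", columns=SAMPLE_KEYS, values=value, sort=True)
    if wide.isna().any().any():
        raise ValidationError("signal matrix has missing (peptide, sample) cells")
    log2 = np.log2(wide.clip(lower=floor))
    mu = log2.mean(axis=1)
    sd = log2.std(axis=1, ddof=1)
    z = log2.sub(mu, axis=0).div(sd.where(sd > 0), axis=0).fillna(0.0)
    return SignalMatrix(log2=log2, zscore=z, floor=floor)
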