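"""Within-chip two-group comparisons.

Chips are technical replicates: per-peptide log2 fold-changes are computed
between the case and control wells of the same chip and then averaged across
chips. Global group differences use nonparametric rank tests, and chip-to-chip
reproducibility is summarized as per-peptide coefficients of variation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from kinoscope.errors import ValidationError
from kinoscope.preprocess import SignalMatrix

CLASS_UP = "up"
CLASS_DOWN = "down"
CLASS_UNCHANGED = "unchanged"


def log2fc(
    matrix: SignalMatrix,
    case_group: str,
    control_group: str,
    cutoff: float = 0.15,
) -> pd.DataFrame:
    """Per-peptide log2 fold-change of case over control, chip by chip.

    Only chips carrying both groups contribute; a chip missing one of the two
    groups is dropped with a warning. The replicate mean classifies each
    peptide as up/down/unchanged against ``cutoff`` (|mean| >= cutoff).

    Returns a frame with one ``log2fc_<chip>`` column per usable chip plus
    ``mean_log2fc`` and ``classification``.
    """
    if cutoff < 0:
        raise ValidationError("cutoff must be >= 0")
    cols = matrix.log2.columns
    for g in (case_group, control_group):
        if g not in cols.get_level_values(0):
            raise ValidationError(f"group {g!r} absent from the signal matrix")
    case_chips = set(cols[cols.get_level_values(0) == case_group].get_level_values(1))
    ctrl_chips = set(cols[cols.get_level_values(0) == control_group].get_level_values(1))
    shared = sorted(case_chips & ctrl_chips)
    skipped = sorted(case_chips ^ ctrl_chips)
    if skipped:
        warnings.warn(
            f"chips without both groups omitted from log2FC: {skipped}", stacklevel=2
        )
    if not shared:
        raise ValidationError(
            f"no chip carries both {case_group!r} and {control_group!r}"
        )

    out = pd.DataFrame(index=matrix.log2.index)
    for chip in shared:
        out[f"log2fc_{chip}"] = (
            matrix.log2[(case_group, chip)] - matrix.log2[(control_group, chip)]
        )
    out["mean_log2fc"] = out.mean(axis=1)
    mean = out["mean_log2fc"]
    out["classification"] = np.select(
        [mean >= cutoff, mean <= -cutoff], [CLASS_UP, CLASS_DOWN], CLASS_UNCHANGED
    )
    return out.reset_index()


def log2fc_reclassify(lfc: pd.DataFrame, cutoff: float) -> pd.DataFrame:
    """Re-derive the classification column from mean_log2fc at a new cutoff."""
    if cutoff < 0:
        raise ValidationError("cutoff must be >= 0")
    out = lfc.copy()
    mean = out["mean_log2fc"]
    out["classification"] = np.select(
        [mean >= cutoff, mean <= -cutoff], [CLASS_UP, CLASS_DOWN], CLASS_UNCHANGED
    )
    return out


def differential_peptides(lfc: pd.DataFrame, direction: str = "both") -> list[str]:
    """Peptides classified differential; direction in {'both', 'up', 'down'}."""
    if direction == "both":
        mask = lfc["classification"] != CLASS_UNCHANGED
    elif direction in (CLASS_UP, CLASS_DOWN):
        mask = lfc["classification"] == direction
    else:
        raise ValidationError(f"direction must be both/up/down, got {direction!r}")
    return sorted(lfc.loc[mask, "peptide_id"])


@dataclass
class GlobalComparison:
    groups: tuple[str, str]
    test: str  # "rank_sum" or "signed_rank"
    statistic: float
    p_value: float
    group_means: dict[str, float]
    n: int

    def to_frame(self) -> pd.DataFrame:
        a, b = self.groups
        return pd.DataFrame(
            [
                {
                    "group_a": a,
                    "group_b": b,
                    "test": self.test,
                    "statistic": self.statistic,
                    "p_value": self.p_value,
                    "mean_a": self.group_means[a],
                    "mean_b": self.group_means[b],
                    "n": self.n,
                }
            ]
        )


def global_test(
    matrix: SignalMatrix, groups: tuple[str, str], paired: bool = True
) -> GlobalComparison:
    """Two-sided rank test on per-peptide group-mean signals.

    Each peptide contributes its mean log2 signal per group (averaged over
    that group's chips). ``paired=True`` runs the Wilcoxon signed-rank test on
    per-peptide differences with zero differences dropped (Wilcoxon's original
    rule; all-zero differences give p = 1). ``paired=False`` runs the rank-sum
    (Mann-Whitney) test. Exact small-sample p-values where scipy supports them.
    """
    a, b = groups
    lvl0 = matrix.log2.columns.get_level_values(0)
    for g in groups:
        if g not in lvl0:
            raise ValidationError(f"group {g!r} absent from the signal matrix")
    xa = matrix.log2.loc[:, lvl0 == a].mean(axis=1)
    xb = matrix.log2.loc[:, lvl0 == b].mean(axis=1)
    means = {a: float(xa.mean()), b: float(xb.mean())}
    if paired:
        diffs = (xa - xb).to_numpy()
        if len(diffs) < 3:
            raise ValidationError("paired test needs >= 3 paired observations")
        nonzero = diffs[diffs != 0]
        if len(nonzero) == 0:
            return GlobalComparison(groups, "signed_rank", 0.0, 1.0, means, len(diffs))
        res = stats.wilcoxon(
            nonzero, zero_method="wilcox", alternative="two-sided", method="auto"
        )
        return GlobalComparison(
            groups, "signed_rank", float(res.statistic), float(res.pvalue), means, len(diffs)
        )
    res = stats.mannwhitneyu(xa.to_numpy(), xb.to_numpy(), alternative="two-sided")
    return GlobalComparison(
        groups, "rank_sum", float(res.statistic), float(res.pvalue), means, len(xa)
    )


def cv_report(
    slopes: pd.DataFrame, keep: list[str] | None = None, groups: list[str] | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Chip-to-chip coefficient of variation of the working signal.

    For each (peptide, group) with >= 2 chips: CV% = 100 * sd / mean (sample
    sd, n-1 denominator). Peptides with mean 0 in a group are excluded from
    that group with a warning. Returns (per-peptide CV table, per-group median
    CV table); medians are over the kept peptides only.
    """
    df = slopes
    if keep is not None:
        df = df[df["peptide_id"].isin(keep)]
    if groups is not None:
        df = df[df["group"].isin(groups)]
    if df.empty:
        raise ValidationError("no signals left for CV report")
    n_chips = df.groupby("group")["chip"].nunique()
    few = n_chips[n_chips < 2]
    if len(few):
        raise ValidationError(f"CV needs >= 2 chips per group; got {few.to_dict()}")

    g = df.groupby(["peptide_id", "group"])["signal"]
    per = pd.DataFrame({"mean": g.mean(), "sd": g.std(ddof=1), "n_chips": g.count()})
    zero = per["mean"] == 0
    if zero.any():
        warnings.warn(
            f"CV undefined (mean 0) for {int(zero.sum())} peptide/group cell(s); excluded",
            stacklevel=2,
        )
        per = per[~zero]
    per["cv_pct"] = 100.0 * per["sd"] / per["mean"]
    per = per.reset_index()
    medians = (
        per.groupby("group")["cv_pct"].median().rename("median_cv_pct").reset_index()
    )
    return per, medians
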