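"""Percentile harmonization of kinase rankings across tools.

Each tool's scores are converted to rank/N percentiles (average ranks for
ties, best kinase at 1.0; lower-is-better scores inverted first), joined in a
common symbol namespace via a user-supplied alias table, and summarized by
mean/median percentile. A kinase is selected when it is reported by at least
``min_tools`` tools and its mean percentile reaches ``min_mean_percentile``.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from kinoscope.errors import ValidationError

logger = logging.getLogger(__name__)

QUARTILE_EDGES = (0.25, 0.5, 0.75)


def krsa_to_scores(krsa_results: pd.DataFrame, tool: str = "KRSA") -> pd.DataFrame:
    """Adapt a resampling result table to the generic tool-score schema.

    Kinases with undefined Z are omitted with a warning.
    """
    bad = krsa_results["z"].isna()
    if bad.any():
        warnings.warn(
            f"{int(bad.sum())} kinase(s) with undefined Z omitted from tool {tool!r}: "
            f"{sorted(krsa_results.loc[bad, 'kinase'])[:5]}",
            stacklevel=2,
        )
    ok = krsa_results[~bad]
    return pd.DataFrame(
        {
            "kinase": ok["kinase"],
            "tool": tool,
            "score": ok["z"],
            "score_direction": "higher_is_better",
        }
    ).reset_index(drop=True)


def percentile_normalize(scores: pd.DataFrame) -> pd.DataFrame:
    """Within-tool percentile = rank / N with average ranks for ties.

    The best-scoring kinase gets exactly 1.0; lower-is-better scores are
    negated before ranking. NaN scores are dropped with a warning. Returns a
    tidy frame (kinase, tool, percentile).
    """
    required = {"kinase", "tool", "score", "score_direction"}
    missing = required - set(scores.columns)
    if missing:
        raise ValidationError(f"tool scores missing columns {sorted(missing)}")
    out = []
    for tool, sub in scores.groupby("tool", sort=True):
        if sub["kinase"].duplicated().any():
            raise ValidationError(f"duplicate kinase entries within tool {tool!r}")
        nan = sub["score"].isna()
        if nan.any():
            warnings.warn(
                f"{int(nan.sum())} NaN score(s) dropped for tool {tool!r}", stacklevel=2
            )
            sub = sub[~nan]
        if sub.empty:
            continue
        directions = set(sub["score_direction"])
        if not directions <= {"higher_is_better", "lower_is_better"}:
            raise ValidationError(f"invalid score_direction for tool {tool!r}")
        vals = sub["score"].to_numpy(dtype=float)
        sign = np.where(sub["score_direction"] == "lower_is_better", -1.0, 1.0)
        ranks = stats.rankdata(vals * sign, method="average")
        out.append(
            pd.DataFrame(
                {"kinase": sub["kinase"], "tool": tool, "percentile": ranks / len(sub)}
            )
        )
    if not out:
        raise ValidationError("no usable tool scores")
    return pd.concat(out, ignore_index=True)


def apply_aliases(percentiles: pd.DataFrame, alias_table: pd.DataFrame | None) -> pd.DataFrame:
    """Map kinase names to a common symbol namespace.

    When two input names collapse to the same symbol within a tool, the better
    (higher) percentile is kept and the collision is logged.
    """
    df = percentiles.copy()
    if alias_table is not None:
        mapping = dict(zip(alias_table["alias"], alias_table["symbol"]))
        df["kinase"] = df["kinase"].map(lambda k: mapping.get(k, k))
    collided = df.duplicated(["kinase", "tool"], keep=False)
    if collided.any():
        for (k, t), sub in df[collided].groupby(["kinase", "tool"]):
            logger.warning(
                "alias collision: %d entries map to %s in tool %s; keeping best percentile",
                len(sub), k, t,
            )
        df = (
            df.sort_values("percentile", ascending=False)
            .drop_duplicates(["kinase", "tool"], keep="first")
            .sort_index()
        )
    return df.reset_index(drop=True)


def quartile_bin(mean_percentile: float) -> str:
    """Quartile label from mean percentile: [0,.25) Q1 ... [.75,1] Q4."""
    for i, edge in enumerate(QUARTILE_EDGES):
        if mean_percentile < edge:
            return f"Q{i + 1}"
    return "Q4"


def harmonize(
    percentiles: pd.DataFrame,
    alias_table: pd.DataFrame | None = None,
    min_tools: int = 2,
    min_mean_percentile: float = 0.75,
) -> pd.DataFrame:
    """Combine per-tool percentiles into one row per kinase.

    Output columns: one ``pct_<tool>`` per tool, ``n_tools``,
    ``mean_percentile``, ``median_percentile`` (over reporting tools only),
    ``selected`` and ``quartile``. Single-tool kinases are retained
    (unselected) for transparency.
    """
    df = apply_aliases(percentiles, alias_table)
    wide = df.pivot(index="kinase", columns="tool", values="percentile")
    wide.columns = [f"pct_{t}" for t in wide.columns]
    out = wide.copy()
    out["n_tools"] = wide.notna().sum(axis=1)
    out["mean_percentile"] = wide.mean(axis=1)
    out["median_percentile"] = wide.median(axis=1)
    out["selected"] = (out["n_tools"] >= min_tools) & (
        out["mean_percentile"] >= min_mean_percentile
    )
    out["quartile"] = out["mean_percentile"].map(quartile_bin)
    out = out.sort_values("mean_percentile", ascending=False)
    return out.reset_index()


def selected_kinases(harmonized: pd.DataFrame) -> set[str]:
    return set(harmonized.loc[harmonized["selected"], "kinase"])


@dataclass
class OverlapSets:
    """Disjoint partition of two selected-kinase sets."""

    common: set[str]
    only_a: set[str]
    only_b: set[str]

    def to_frame(self, label_a: str = "A", label_b: str = "B") -> pd.DataFrame:
        rows = [("common", k) for k in sorted(self.common)]
        rows += [(f"only_{label_a}", k) for k in sorted(self.only_a)]
        rows += [(f"only_{label_b}", k) for k in sorted(self.only_b)]
        return pd.DataFrame(rows, columns=["set", "kinase"])


def overlap(selected_a, selected_b) -> OverlapSets:
    """Common / only-A / only-B partition of two selected sets."""
    a, b = set(selected_a), set(selected_b)
    return OverlapSets(common=a & b, only_a=a - b, only_b=b - a)
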