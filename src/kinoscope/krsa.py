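"""Resampling-based upstream-kinase enrichment.

Each kinase is scored by how many of its mapped peptides fall in the
differential set, standardized against a null built by repeatedly drawing
random peptide sets of the same size (without replacement) from the QC-passed
universe:

    Z = (observed_hits - null_mean) / null_sd

As iterations grow the null moments converge to the hypergeometric
mean n*m/N and sd sqrt(n * m/N * (1 - m/N) * (N - n)/(N - 1)).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from kinoscope.errors import ValidationError
from kinoscope.io import check_map_against_universe

UNDEFINED_REASON_ALL = "kinase maps to the whole universe (null sd = 0)"
UNDEFINED_REASON_NONE = "kinase maps to no universe peptide"
UNDEFINED_REASON_SD0 = "null sd = 0"

_CHUNK = 20_000


def krsa_score(
    differential_peptides,
    universe,
    kinase_map: pd.DataFrame,
    iterations: int = 2000,
    seed: int | None = None,
    chunk_size: int = _CHUNK,
) -> pd.DataFrame:
    """Score every kinase in ``kinase_map`` against a resampling null.

    Each iteration draws ``len(differential_peptides)`` peptides uniformly
    without replacement from ``universe`` and counts hits per kinase. Results
    are sorted by Z descending; kinases whose null sd is 0 (mapping to all or
    none of the universe) get Z = NaN with a ``z_undefined_reason``.

    Deterministic given ``seed``; invariant to the input order of the
    universe and differential sets (both are canonicalized by sorting).
    """
    if iterations < 100:
        raise ValidationError("iterations must be >= 100")
    if seed is None:
        raise ValidationError("a seed is required for reproducible resampling")
    universe = sorted(set(map(str, universe)))
    diff = sorted(set(map(str, differential_peptides)))
    if not universe:
        raise ValidationError("empty universe")
    extra = set(diff) - set(universe)
    if extra:
        raise ValidationError(
            f"differential peptides outside the universe: {sorted(extra)[:5]}"
        )

    kmap = check_map_against_universe(kinase_map, universe)
    kinases = sorted(set(kinase_map["kinase"]))
    pos = {p: i for i, p in enumerate(universe)}
    N, n = len(universe), len(diff)

    # kinase x universe membership
    member = np.zeros((len(kinases), N), dtype=bool)
    krow = {k: i for i, k in enumerate(kinases)}
    for k, p in kmap.itertuples(index=False):
        member[krow[k], pos[p]] = True
    m = member.sum(axis=1)

    ind = np.zeros(N, dtype=bool)
    ind[[pos[p] for p in diff]] = True
    observed = member.astype(np.int64) @ ind.astype(np.int64)

    rng = np.random.default_rng(seed)
    memberf = member.astype(np.float64).T  # N x K
    total = np.zeros(len(kinases))
    total_sq = np.zeros(len(kinases))
    done = 0
    while done < iterations:
        c = min(chunk_size, iterations - done)
        # c random n-subsets of the universe via argpartition of uniforms
        u = rng.random((c, N))
        pick = np.argpartition(u, n - 1, axis=1)[:, :n] if n else np.empty((c, 0), int)
        sel = np.zeros((c, N), dtype=np.float64)
        if n:
            sel[np.arange(c)[:, None], pick] = 1.0
        hits = sel @ memberf  # c x K
        total += hits.sum(axis=0)
        total_sq += (hits**2).sum(axis=0)
        done += c

    null_mean = total / iterations
    var = (total_sq - iterations * null_mean**2) / (iterations - 1)
    null_sd = np.sqrt(np.clip(var, 0.0, None))

    with np.errstate(invalid="ignore", divide="ignore"):
        z = np.where(null_sd > 0, (observed - null_mean) / null_sd, np.nan)
    reasons = np.where(
        m == 0,
        UNDEFINED_REASON_NONE,
        np.where(m == N, UNDEFINED_REASON_ALL, np.where(null_sd == 0, UNDEFINED_REASON_SD0, "")),
    )

    out = pd.DataFrame(
        {
            "kinase": kinases,
            "observed": observed.astype(int),
            "null_mean": null_mean,
            "null_sd": null_sd,
            "z": z,
            "z_undefined_reason": reasons,
            "n_mapped": m.astype(int),
            "n_differential": n,
            "n_universe": N,
            "iterations": iterations,
            "seed": seed,
        }
    )
    out = out.sort_values("z", ascending=False, na_position="last", kind="mergesort")
    return out.reset_index(drop=True)


def krsa_direction_split(
    lfc: pd.DataFrame,
    universe,
    kinase_map: pd.DataFrame,
    iterations: int = 2000,
    seed: int | None = None,
) -> dict[str, pd.DataFrame]:
    """Run :func:`krsa_score` separately on the up- and down-classified sets.

    Empty direction sets are skipped with a warning; the returned dict has
    keys only for directions that were scored.
    """
    from kinoscope.differential import differential_peptides

    out: dict[str, pd.DataFrame] = {}
    for direction in ("up", "down"):
        peps = differential_peptides(lfc, direction)
        if not peps:
            warnings.warn(f"no {direction}-classified peptides; skipped", stacklevel=2)
            continue
        out[direction] = krsa_score(
            peps, universe, kinase_map, iterations=iterations, seed=seed
        )
    return out


def hypergeometric_null(N: int, m: int, n: int) -> tuple[float, float]:
    """Closed-form null moments for m mapped peptides, n draws from N."""
    if N < 1:
        raise ValidationError("N must be >= 1")
    p = m / N
    mean = n * p
    var = n * p * (1 - p) * (N - n) / (N - 1) if N > 1 else 0.0
    return mean, float(np.sqrt(var))
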