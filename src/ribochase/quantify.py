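"""Relative quantification of qPCR Ct tables (comparative-Ct method).

Converts raw cycle-threshold values into relative abundances with the
classic ddCt calculus at amplification efficiency exactly 2:

    dCt  = mean Ct(target) - mean Ct(reference)          per sample
    ddCt = dCt(t) - dCt(calibrator)                      per series
    rq   = 2 ** (-ddCt)

Technical replicates are averaged on the Ct scale (geometric averaging
on the abundance scale); biological replicates are kept as separate
series so downstream fitting can pool them.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

RQ_COLUMNS = ["condition", "region", "compartment", "time_min", "bio_rep", "rq"]


class QuantifyError(ValueError):
    """A series lacks a reference or calibrator measurement."""


def delta_delta_ct(
    records: pd.DataFrame,
    reference_target: str = "16S",
    calibrator_time: float = 0.0,
) -> pd.DataFrame:
    """Relative quantities from a Ct table via the ddCt method.

    Parameters
    ----------
    records
        Ct table with columns condition, region, compartment, time_min,
        bio_rep, tech_rep, target, ct (the dialect written by
        :func:`ribochase.simulate.simulate_chase`).
    reference_target
        Target label of the reference gene; reference wells are matched
        to target wells by (condition, bio_rep, time_min), i.e. per RNA
        sample, regardless of region.
    calibrator_time
        Timepoint whose relative quantity defines 1 for each series
        (condition, region, bio_rep).

    Returns
    -------
    DataFrame with columns ``RQ_COLUMNS``; rq is dimensionless and > 0,
    equal to 1 at the calibrator time by construction.

    Raises
    ------
    QuantifyError
        If a series has no reference wells or no calibrator timepoint.
    Warns on (and drops) non-finite Ct values.
    """
    df = records.copy()
    bad = ~np.isfinite(df["ct"].to_numpy(dtype=float))
    if bad.any():
        warnings.warn(f"dropping {int(bad.sum())} non-finite Ct rows", stacklevel=2)
        df = df[~bad]

    is_ref = df["target"] == reference_target
    ref = (
        df[is_ref]
        .groupby(["condition", "bio_rep", "time_min"], as_index=False)["ct"]
        .mean()
        .rename(columns={"ct": "ref_ct"})
    )
    tgt = (
        df[~is_ref]
        .groupby(
            ["condition", "region", "compartment", "bio_rep", "time_min"],
            as_index=False,
        )["ct"]
        .mean()
    )
    merged = tgt.merge(ref, on=["condition", "bio_rep", "time_min"], how="left")
    missing = merged[merged["ref_ct"].isna()]
    if len(missing):
        key = missing.iloc[0]
        raise QuantifyError(
            "no reference-gene Ct for sample "
            f"(condition={key['condition']!r}, bio_rep={key['bio_rep']}, "
            f"time_min={key['time_min']})"
        )
    merged["dct"] = merged["ct"] - merged["ref_ct"]

    series_keys = ["condition", "region", "compartment", "bio_rep"]
    cal = merged[merged["time_min"] == calibrator_time][series_keys + ["dct"]].rename(
        columns={"dct": "dct_cal"}
    )
    out = merged.merge(cal, on=series_keys, how="left")
    missing = out[out["dct_cal"].isna()]
    if len(missing):
        key = missing.iloc[0]
        raise QuantifyError(
            f"series (condition={key['condition']!r}, region={key['region']!r}, "
            f"bio_rep={key['bio_rep']}) has no calibrator timepoint "
            f"t={calibrator_time}"
        )
    out["rq"] = 2.0 ** -(out["dct"] - out["dct_cal"])
    return out[RQ_COLUMNS].sort_values(RQ_COLUMNS[:5]).reset_index(drop=True)


def normalize_signal(
    values,
    reference_values,
    baseline_index: int | None = None,
) -> np.ndarray:
    """Elementwise ratio of a signal to a reference signal.

    Used for activity readouts normalised to their pre-treatment value
    and protein signals normalised to a loading control.  With
    ``baseline_index`` the ratios are additionally rescaled so that the
    designated element equals 1.
    """
    v = np.asarray(values, dtype=float)
    r = np.asarray(reference_values, dtype=float)
    if v.shape != r.shape:
        raise ValueError(f"shape mismatch: {v.shape} vs {r.shape}")
    if v.size and not (r > 0).all():
        raise ValueError("reference values must be strictly positive")
    out = v / r if v.size else v.copy()
    if baseline_index is not None and v.size:
        out = out / out[baseline_index]
    return out
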