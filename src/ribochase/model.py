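"""Steady-state synthesis/decay calculus and termination inference.

At steady state a transcript's level is Int = alpha / lambda, where
alpha is its synthesis rate and lambda its first-order decay constant.
For two species i, j the ratio of synthesis rates therefore factors as

    FCsynt(i, j) = alpha_i / alpha_j = (Int_i / Int_j) * (lambda_i / lambda_j)

— an intensity fold change times a decay-constant fold change, both
measurable.  Under a single shared promoter, FCsynt(UTR, ORF) > 1 means
some polymerases that made the 5' UTR never made the ORF, i.e. premature
termination; the terminating fraction is 1 - 1/FCsynt and the full-length
read-through fraction is its complement.

Internal arithmetic is always on unrounded values; rounding happens only
at report emission (fold changes >= 1 to one decimal, < 1 to two
decimals, percentages to one decimal, half away from zero).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from decimal import Decimal, ROUND_HALF_UP

import numpy as np
import pandas as pd

LN2 = float(np.log(2.0))


def round_fold_change(x: float) -> float:
    """Report rounding for fold changes: >= 1 to one decimal, < 1 to two."""
    if x <= 0 or not np.isfinite(x):
        raise ValueError(f"fold change must be positive and finite, got {x}")
    q = Decimal("0.1") if x >= 1 else Decimal("0.01")
    return float(Decimal(repr(float(x))).quantize(q, rounding=ROUND_HALF_UP))


def round_percent(x: float) -> float:
    """Report rounding for percentages: one decimal, half away from zero."""
    return float(Decimal(repr(float(x))).quantize(Decimal("0.1"), rounding=ROUND_HALF_UP))


@dataclass(frozen=True)
class CompartmentMeasurement:
    """Steady-state intensity and decay rate of one probed compartment.

    Exactly one of ``lam`` (min^-1) and ``t_half`` (min) may be given;
    the other is derived through lambda * t_half = ln 2.
    """

    label: str
    intensity: float
    lam: float | None = None
    t_half: float | None = None

    def __post_init__(self):
        if not self.intensity > 0:
            raise ValueError(f"{self.label}: intensity must be > 0")
        if (self.lam is None) == (self.t_half is None):
            raise ValueError(f"{self.label}: give exactly one of lam and t_half")
        if self.lam is None:
            if not self.t_half > 0:
                raise ValueError(f"{self.label}: t_half must be > 0")
            object.__setattr__(self, "lam", LN2 / self.t_half)
        else:
            if not self.lam > 0:
                raise ValueError(f"{self.label}: lam must be > 0")
            object.__setattr__(self, "t_half", LN2 / self.lam)

    @property
    def alpha_hat(self) -> float:
        """Implied absolute synthesis rate Int * lambda (arbitrary units/min)."""
        return self.intensity * self.lam


@dataclass(frozen=True)
class TerminationFraction:
    """Premature-termination fraction with an evidence flag.

    ``evidence`` is False when the synthesis ratio was < 1, in which case
    the fraction is clamped to 0 (no support for termination).
    """

    fraction: float
    evidence: bool = True

    @property
    def readthrough(self) -> float:
        return 1.0 - self.fraction

    @property
    def percent(self) -> float:
        return 100.0 * self.fraction

    def __float__(self) -> float:
        return self.fraction


@dataclass(frozen=True)
class SynthesisRatioResult:
    """One column of the synthesis-rate table: the three fold changes."""

    fc_intensity: float
    fc_decay: float
    fc_synthesis: float
    termination: TerminationFraction | None = None


def synthesis_ratio(fc_intensity: float, fc_decay: float) -> SynthesisRatioResult:
    """Synthesis-rate fold change FCsynt = FC_intensity * FC_decay.

    Also attaches the termination fraction implied when the ratio is read
    as UTR-over-ORF under a single promoter (callers comparing the same
    compartment across conditions should ignore it).
    """
    if not (fc_intensity > 0 and fc_decay > 0):
        raise ValueError("fold changes must be > 0")
    fc_synth = fc_intensity * fc_decay
    return SynthesisRatioResult(
        fc_intensity=fc_intensity,
        fc_decay=fc_decay,
        fc_synthesis=fc_synth,
        termination=termination_fraction(fc_synth),
    )


def termination_fraction(fc_synthesis_utr_over_orf: float) -> TerminationFraction:
    """Fraction of initiating polymerases terminating before the ORF.

    With a single promoter, alpha_UTR counts all initiations and
    alpha_ORF only read-through, so FCsynt = 1 / (1 - f) and
    f = 1 - 1/FCsynt.  A ratio < 1 carries no evidence of termination
    and returns 0 with ``evidence=False``.
    """
    fc = fc_synthesis_utr_over_orf
    if not fc > 0:
        raise ValueError(f"synthesis ratio must be > 0, got {fc}")
    if fc < 1.0:
        return TerminationFraction(0.0, evidence=False)
    return TerminationFraction(1.0 - 1.0 / fc, evidence=True)


def decay_fc_from_half_lives(t_half_num: float, t_half_den: float) -> float:
    """Decay-constant ratio lambda_num / lambda_den from two half-lives.

    Since lambda = ln2 / t_half, the ratio equals t_half_den / t_half_num.
    """
    if not (t_half_num > 0 and t_half_den > 0):
        raise ValueError("half-lives must be > 0")
    return t_half_den / t_half_num


_ROW_LABELS = [
    "FC of intensity",
    "FC of decay constant",
    "FC of synthesis rate",
    "Termination after UTR",
]
_COL_LABELS = ["mock UTR/ORF", "UV UTR/ORF", "UTR UV/mock"]


@dataclass(frozen=True)
class SynthesisRateReport:
    """The reconstructed synthesis-rate table.

    Columns: UTR vs ORF under mock, UTR vs ORF under UV, and UTR under
    UV vs mock.  The first two columns carry termination fractions; the
    third is read as a transcription-rate change (its reciprocal is the
    factor by which transcription dropped).
    """

    mock: SynthesisRatioResult
    uv: SynthesisRatioResult
    utr_uv_mock: SynthesisRatioResult

    @property
    def transcription_rate_reduction(self) -> float:
        """Factor by which the UV condition reduced initiation."""
        return 1.0 / self.utr_uv_mock.fc_synthesis

    def formatted(self) -> pd.DataFrame:
        """Report table with the publication rounding applied."""
        cols = {}
        for label, col, has_term in (
            (_COL_LABELS[0], self.mock, True),
            (_COL_LABELS[1], self.uv, True),
            (_COL_LABELS[2], self.utr_uv_mock, False),
        ):
            cols[label] = [
                round_fold_change(col.fc_intensity),
                round_fold_change(col.fc_decay),
                round_fold_change(col.fc_synthesis),
                f"{round_percent(col.termination.percent)}%" if has_term else "NA",
            ]
        return pd.DataFrame(cols, index=_ROW_LABELS)

    def to_json(self) -> str:
        payload = {
            label: {
                "fc_intensity": col.fc_intensity,
                "fc_decay": col.fc_decay,
                "fc_synthesis": col.fc_synthesis,
                "termination_fraction": (
                    col.termination.fraction if has_term else None
                ),
            }
            for label, col, has_term in (
                (_COL_LABELS[0], self.mock, True),
                (_COL_LABELS[1], self.uv, True),
                (_COL_LABELS[2], self.utr_uv_mock, False),
            )
        }
        payload["transcription_rate_reduction"] = self.transcription_rate_reduction
        return json.dumps(payload, indent=2)

    def to_tsv(self, path) -> None:
        self.formatted().to_csv(path, sep="\t", index_label="")


def _column(
    name: str,
    fc_intensity: float | None,
    fc_decay: float | None,
    half_lives: tuple[float, float] | None,
    missing: list[str],
) -> SynthesisRatioResult | None:
    if fc_intensity is None:
        missing.append(f"{name}: FC of intensity")
    if fc_decay is None and half_lives is None:
        missing.append(f"{name}: FC of decay constant or half-life pair")
    if missing:
        return None
    if fc_decay is None:
        fc_decay = decay_fc_from_half_lives(*half_lives)
    return synthesis_ratio(fc_intensity, fc_decay)


def synthesis_rate_report(
    *,
    fc_int_mock: float | None = None,
    fc_int_uv: float | None = None,
    fc_int_utr_uv_mock: float | None = None,
    fc_decay_mock: float | None = None,
    mock_half_lives: tuple[float, float] | None = None,
    fc_decay_uv: float | None = None,
    uv_half_lives: tuple[float, float] | None = None,
    fc_decay_utr_uv_mock: float | None = None,
    utr_half_lives: tuple[float, float] | None = None,
) -> SynthesisRateReport:
    """Build the synthesis-rate report from fold-change inputs.

    Each column needs its intensity fold change plus either a
    decay-constant fold change or a (numerator, denominator) half-life
    pair — e.g. ``mock_half_lives=(t_half_UTR, t_half_ORF)`` gives
    lambda_UTR / lambda_ORF.  For the third column the numerator is the
    UV condition: ``utr_half_lives=(t_half_UV, t_half_mock)``.

    Raises
    ------
    ValueError
        Listing every missing cell if the input is incomplete.
    """
    missing: list[str] = []
    mock = _column("mock UTR/ORF", fc_int_mock, fc_decay_mock, mock_half_lives, missing)
    uv = _column("UV UTR/ORF", fc_int_uv, fc_decay_uv, uv_half_lives, missing)
    utr = _column(
        "UTR UV/mock", fc_int_utr_uv_mock, fc_decay_utr_uv_mock, utr_half_lives, missing
    )
    if missing:
        raise ValueError("incomplete report input; missing: " + "; ".join(missing))
    return SynthesisRateReport(mock=mock, uv=uv, utr_uv_mock=utr)


def synthesis_report_from_measurements(
    measurements: dict[tuple[str, str], CompartmentMeasurement],
) -> SynthesisRateReport:
    """Report from four absolute measurements keyed (condition, compartment).

    Conditions are "mock" and "uv"; compartments "UTR" and "ORF".  Fold
    changes are formed from the unrounded intensities and decay
    constants; absolute synthesis rates are available per measurement as
    ``CompartmentMeasurement.alpha_hat``.
    """
    required = [(c, k) for c in ("mock", "uv") for k in ("UTR", "ORF")]
    missing = [f"{c}/{k}" for c, k in required if (c, k) not in measurements]
    if missing:
        raise ValueError("incomplete report input; missing: " + "; ".join(missing))
    m = measurements
    return synthesis_rate_report(
        fc_int_mock=m[("mock", "UTR")].intensity / m[("mock", "ORF")].intensity,
        fc_decay_mock=m[("mock", "UTR")].lam / m[("mock", "ORF")].lam,
        fc_int_uv=m[("uv", "UTR")].intensity / m[("uv", "ORF")].intensity,
        fc_decay_uv=m[("uv", "UTR")].lam / m[("uv", "ORF")].lam,
        fc_int_utr_uv_mock=m[("uv", "UTR")].intensity / m[("mock", "UTR")].intensity,
        fc_decay_utr_uv_mock=m[("uv", "UTR")].lam / m[("mock", "UTR")].lam,
    )
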