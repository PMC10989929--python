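"""Generative model of the chase experiment and its steady state.

The model: a single promoter initiates transcription at rate ``alpha``
(initiations/min).  A fraction ``f_term`` of initiating polymerases
terminates within the 5' UTR, so the UTR segment is synthesised by every
initiation while the downstream ORF segment is synthesised only by the
read-through fraction ``1 - f_term``.  Each segment decays with its own
first-order constant (``lambda_utr``, ``lambda_orf``; min^-1).  At steady
state the abundance of a species with synthesis rate a and decay constant
l is a / l.

After transcription arrest at t = 0 (rifampicin addition) the relative
abundance of each segment follows N(t) = exp(-lambda * t).  The qPCR
readout maps abundance to a cycle-threshold value: one halving of template
costs one cycle at amplification efficiency 2, so the emitted Ct is

    ct = ref_ct_mean + baseline_offset - log2(N(t) * Int) + eps

with eps ~ Normal(0, ct_noise_sd) independent per well.  The reference
gene (16S rRNA) is treated as decay-free on the chase timescale and emits
``ref_ct_mean + eps``.  Noise is additive on the Ct scale, i.e. log-normal
on the abundance scale, matching the error structure of real qPCR.

All randomness flows from a single top-level seed through deterministic
per-stream substreams (`numpy.random.SeedSequence.spawn`).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

QPCR_COLUMNS = [
    "sample",
    "condition",
    "region",
    "compartment",
    "time_min",
    "bio_rep",
    "tech_rep",
    "target",
    "ct",
]

#: Default chase sampling grid (minutes after transcription arrest).
DEFAULT_TIMEPOINTS = (0.0, 5.0, 10.0, 30.0)


class ParameterError(ValueError):
    """A simulation parameter is outside its admissible domain."""


@dataclass(frozen=True)
class SimulationParams:
    """Parameters of the promoter -> termination -> decay model.

    Parameters
    ----------
    alpha
        Transcription initiation rate (initiations/min), > 0.
    f_term
        Fraction of initiations terminating within the 5' UTR, in [0, 1).
    lambda_utr, lambda_orf
        First-order decay constants of the UTR and ORF segments (min^-1), > 0.
    timepoints
        Chase sampling times in minutes; sorted, first element 0.
    n_regions_per_compartment
        Number of independently probed segments per compartment (the study
        design probes two regions each in UTR and ORF).
    n_bio_reps, n_tech_reps
        Biological and technical replication.
    ct_noise_sd
        Standard deviation of the additive Ct noise, in cycles, >= 0.
    ref_ct_mean
        Mean Ct of the (stable) reference gene.
    baseline_offset
        Cycles separating the reference gene from a target of unit
        abundance; fixes the absolute Ct scale of the targets.
    seed
        Top-level RNG seed; all substreams derive from it.
    """

    alpha: float = 1.0
    f_term: float = 0.0
    lambda_utr: float = np.log(2) / 3.1
    lambda_orf: float = np.log(2) / 7.2
    timepoints: tuple[float, ...] = DEFAULT_TIMEPOINTS
    n_regions_per_compartment: int = 2
    n_bio_reps: int = 3
    n_tech_reps: int = 3
    ct_noise_sd: float = 0.15
    ref_ct_mean: float = 10.0
    baseline_offset: float = 12.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.alpha > 0:
            raise ParameterError(f"alpha must be > 0, got {self.alpha}")
        if not (0 <= self.f_term < 1):
            raise ParameterError(f"f_term must be in [0, 1), got {self.f_term}")
        for name in ("lambda_utr", "lambda_orf"):
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be > 0, got {getattr(self, name)}")
        tp = tuple(float(t) for t in self.timepoints)
        if len(tp) == 0 or tp[0] != 0.0 or any(t < 0 for t in tp):
            raise ParameterError("timepoints must be non-negative and start at 0")
        if list(tp) != sorted(tp):
            raise ParameterError("timepoints must be sorted")
        object.__setattr__(self, "timepoints", tp)
        for name in ("n_regions_per_compartment", "n_bio_reps", "n_tech_reps"):
            if int(getattr(self, name)) < 1:
                raise ParameterError(f"{name} must be a positive integer")
        if self.ct_noise_sd < 0:
            raise ParameterError("ct_noise_sd must be >= 0")

    def with_(self, **kwargs) -> "SimulationParams":
        """Return a copy with the given fields replaced."""
        return replace(self, **kwargs)

    def decay_constant(self, compartment: str) -> float:
        if compartment == "UTR":
            return self.lambda_utr
        if compartment == "ORF":
            return self.lambda_orf
        raise ParameterError(f"unknown compartment {compartment!r}")


@dataclass(frozen=True)
class SteadyState:
    """Steady-state abundances of the two probed compartments.

    ``int_utr = alpha / lambda_utr`` (every initiation makes the UTR) and
    ``int_orf = (1 - f_term) * alpha / lambda_orf`` (only read-through
    makes the ORF).  Arbitrary units.
    """

    int_utr: float
    int_orf: float

    def intensity(self, compartment: str) -> float:
        return self.int_utr if compartment == "UTR" else self.int_orf


def steady_state_abundance(params: SimulationParams) -> SteadyState:
    """Steady-state abundance of UTR and ORF segments under ``params``.

    The UTR level is alpha / lambda_utr; the ORF level is
    (1 - f_term) * alpha / lambda_orf.
    """
    return SteadyState(
        int_utr=params.alpha / params.lambda_utr,
        int_orf=(1.0 - params.f_term) * params.alpha / params.lambda_orf,
    )


def _spawn_rng(seed: int, stream: int) -> np.random.Generator:
    """Deterministic substream `stream` of the top-level `seed`."""
    children = np.random.SeedSequence(seed).spawn(stream + 1)
    return np.random.default_rng(children[stream])


def simulate_chase(
    params: SimulationParams,
    condition: str = "mock",
    reference_target: str = "16S",
    target: str = "rne",
) -> pd.DataFrame:
    """Simulate a rifampicin-chase RT-qPCR Ct table.

    For every compartment (UTR/ORF), probed region, biological replicate,
    timepoint and technical replicate one target Ct is emitted; reference
    wells (one per technical replicate of each RNA sample) carry the
    stable reference gene.  Deterministic given ``params.seed``.

    Returns a DataFrame with columns ``QPCR_COLUMNS``; reference rows have
    ``compartment == "reference"`` and an empty region label.
    """
    rng = _spawn_rng(params.seed, 0)
    ss = steady_state_abundance(params)
    rows: list[tuple] = []
    times = params.timepoints

    for bio in range(1, params.n_bio_reps + 1):
        for t in times:
            sample = f"{condition}_b{bio}_t{t:g}"
            # reference gene: decay-free, one well per technical replicate
            for tech in range(1, params.n_tech_reps + 1):
                ct = params.ref_ct_mean + rng.normal(0.0, params.ct_noise_sd)
                rows.append(
                    (sample, condition, "", "reference", t, bio, tech, reference_target, ct)
                )
            for compartment in ("UTR", "ORF"):
                lam = params.decay_constant(compartment)
                abundance = ss.intensity(compartment) * np.exp(-lam * t)
                true_ct = (
                    params.ref_ct_mean + params.baseline_offset - np.log2(abundance)
                )
                for region_i in range(1, params.n_regions_per_compartment + 1):
                    region = f"{compartment}-{region_i}"
                    for tech in range(1, params.n_tech_reps + 1):
                        ct = true_ct + rng.normal(0.0, params.ct_noise_sd)
                        rows.append(
                            (sample, condition, region, compartment, t, bio, tech, target, ct)
                        )
    return pd.DataFrame(rows, columns=QPCR_COLUMNS)


def simulate_intensity_fc(
    params_mock: SimulationParams,
    params_uv: SimulationParams,
    log_noise_sd: float = 0.0,
) -> pd.DataFrame:
    """Steady-state intensity fold changes between compartments/conditions.

    Emits FC(UTR/ORF) within each condition and FC(UV/mock) within each
    compartment, computed from :func:`steady_state_abundance`.  With
    ``log_noise_sd`` > 0 each of the four underlying intensities is
    multiplied by an independent log-normal factor exp(N(0, log_noise_sd))
    before the ratios are formed (substream 1 of the mock seed).

    Returns a DataFrame with columns comparison, numerator, denominator, fc.
    """
    ss = {"mock": steady_state_abundance(params_mock), "uv": steady_state_abundance(params_uv)}
    ints = {
        (cond, comp): ss[cond].intensity(comp)
        for cond in ("mock", "uv")
        for comp in ("UTR", "ORF")
    }
    if log_noise_sd > 0:
        rng = _spawn_rng(params_mock.seed, 1)
        ints = {k: v * np.exp(rng.normal(0.0, log_noise_sd)) for k, v in ints.items()}
    rows = [
        ("UTR/ORF mock", "UTR@mock", "ORF@mock", ints[("mock", "UTR")] / ints[("mock", "ORF")]),
        ("UTR/ORF uv", "UTR@uv", "ORF@uv", ints[("uv", "UTR")] / ints[("uv", "ORF")]),
        ("UV/mock UTR", "UTR@uv", "UTR@mock", ints[("uv", "UTR")] / ints[("mock", "UTR")]),
        ("UV/mock ORF", "ORF@uv", "ORF@mock", ints[("uv", "ORF")] / ints[("mock", "ORF")]),
    ]
    return pd.DataFrame(rows, columns=["comparison", "numerator", "denominator", "fc"])


@dataclass(frozen=True)
class PlantedSequence:
    """A synthetic RNA with known cleavage signatures planted in it."""

    sequence: str
    site_bonds: tuple[int, ...]
    u_tract: tuple[int, int] | None


def simulate_sequence_with_sites(
    length: int,
    site_positions: Sequence[int] = (),
    u_tract: tuple[int, int] | None = None,
    seed: int = 0,
) -> PlantedSequence:
    """Random RNA string with planted AU-clamp motifs and one U-tract.

    Each entry of ``site_positions`` is a bond index b (the phosphodiester
    bond between residues b and b+1, 1-based): the generator plants A at
    residues b-2 and b-3 (the -3/-4 positions upstream of the bond) and U
    at residue b+2, so a scanner applying both rules reports b.
    ``u_tract`` is a 1-based inclusive interval forced to U.

    Background residues are drawn from {C, G} only, so planted motifs are
    the only rule matches and the planted U-tract is the only U-run — a
    fixture property, not a model of real base composition.

    Raises
    ------
    ValueError
        If planted features demand two different bases at one position,
        or a planted feature falls outside the sequence.
    """
    want: dict[int, str] = {}

    def _require(pos: int, base: str, what: str) -> None:
        if not 1 <= pos <= length:
            raise ValueError(f"{what} needs position {pos} outside sequence of length {length}")
        if want.get(pos, base) != base:
            raise ValueError(
                f"conflicting plants at position {pos}: {want[pos]} vs {base} ({what})"
            )
        want[pos] = base

    for b in site_positions:
        if not (3 <= b <= length - 2):
            raise ValueError(f"bond {b} leaves no room for the AU clamp in length {length}")
        _require(b - 2, "A", f"site bond {b} (-3)")
        if b - 3 >= 1:
            _require(b - 3, "A", f"site bond {b} (-4)")
        _require(b + 2, "U", f"site bond {b} (+2)")
    if u_tract is not None:
        start, end = u_tract
        if start > end:
            raise ValueError(f"u_tract interval reversed: {u_tract}")
        for pos in range(start, end + 1):
            _require(pos, "U", "u_tract")
        # keep the planted tract maximal: flanks must not be U
        for pos in (start - 1, end + 1):
            if 1 <= pos <= length and want.get(pos) == "U":
                raise ValueError("u_tract flank forced to U by another plant")

    rng = np.random.default_rng(seed)
    background = rng.choice(list("CG"), size=length)
    residues = [want.get(i + 1, background[i]) for i in range(length)]
    return PlantedSequence(
        sequence="".join(residues),
        site_bonds=tuple(int(b) for b in site_positions),
        u_tract=u_tract,
    )
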