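"""Stoichiometry inference from flux directions at clamped voltages.

The logic of the reversal-potential experiment: for a candidate coupling of
n protons per peptide the equilibrium voltage is known in closed form, so an
observed acidification at a clamped voltage V implies the true reversal
potential lies above V (equivalently, excludes every n whose reversal is at
or below V), an alkalinization implies the converse, and a no-net-flux
observation points at candidates whose reversal sits within a small
tolerance of V.  Intersecting these constraints over a voltage series
brackets n; a unique no-net-flux match gives a point estimate.

Directional calls are treated as hard constraints (they are large, easily
classified signals); no-net-flux calls are treated as soft evidence — they
nominate candidates but never exclude any, because at high noise a small
genuine flux is indistinguishable from none.  This mirrors the practical
ambiguity between closely spaced reversal potentials (e.g. 5 vs 6 protons,
-24 vs -20 mV for a 100-fold gradient), which the estimate reports through
its ``ambiguous`` flag rather than hiding.
"""

from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Sequence

import numpy as np

from .exceptions import InconsistentCallsError, InvalidInputError
from .simulate import (
    AssayEvent,
    AssayProtocol,
    LiposomeParams,
    SubstrateSpec,
    simulate_replicates,
)
from .thermo import (
    DEFAULT_CONSTANTS,
    AssayConditions,
    Stoichiometry,
    ThermoConstants,
    required_k_out,
    reversal_potential,
)
from .traces import DEFAULT_WINDOW, WindowStat, compute_ratio, normalize, window_stats

__all__ = [
    "FluxDirection",
    "FluxCall",
    "VoltagePlanEntry",
    "StoichiometryEstimate",
    "RecoveryReport",
    "classify_flux",
    "design_voltage_series",
    "infer_stoichiometry",
    "end_to_end_recovery",
    "DEFAULT_CANDIDATES",
]

#: Candidate proton counts scanned by default (m fixed at one peptide).
DEFAULT_CANDIDATES = tuple(range(1, 11))


class FluxDirection(str, Enum):
    ACIDIFICATION = "acidification"
    NO_NET_FLUX = "no_net_flux"
    ALKALINIZATION = "alkalinization"


@dataclass(frozen=True)
class FluxCall:
    """Classified proton-flux direction at one clamped voltage."""

    direction: FluxDirection
    effect_size: float  # |mean F_R - 1| at the readout window
    threshold_used: float


@dataclass(frozen=True)
class VoltagePlanEntry:
    """One row of the designed voltage series: the candidate stoichiometry,
    its reversal potential, and the external K+ that clamps it."""

    candidate: Stoichiometry
    target_voltage: float
    k_out_required: float


@dataclass(frozen=True)
class StoichiometryEstimate:
    """Bracket (and optional point estimate) for the proton count n at
    m = 1 peptide per cycle."""

    lower_n: int | None
    upper_n: int | None
    point_n: int | None
    ambiguous: bool

    def contains(self, n: int) -> bool:
        if self.lower_n is None or self.upper_n is None:
            return False
        return self.lower_n <= n <= self.upper_n


def classify_flux(
    stat: WindowStat, baseline_sd: float, k_sigma: float = 2.0
) -> FluxCall:
    """Call the flux direction from a normalized window statistic.

    The mean F_R is compared against 1 with a noise band of
    ``k_sigma * baseline_sd`` (baseline_sd estimated from the
    pre-valinomycin segment of the normalized traces): below the band is
    acidification (inward proton flux), above is alkalinization, inside is
    no net flux.
    """
    if not baseline_sd > 0:
        raise InvalidInputError("baseline_sd must be positive")
    if k_sigma <= 0:
        raise InvalidInputError("k_sigma must be positive")
    threshold = k_sigma * baseline_sd
    deviation = stat.mean_f_r - 1.0
    if deviation < -threshold:
        direction = FluxDirection.ACIDIFICATION
    elif deviation > threshold:
        direction = FluxDirection.ALKALINIZATION
    else:
        direction = FluxDirection.NO_NET_FLUX
    return FluxCall(direction, abs(deviation), threshold)


def design_voltage_series(
    cond: AssayConditions,
    candidates: Sequence[Stoichiometry],
    k_in: float | None = None,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> list[VoltagePlanEntry]:
    """Plan the clamped-voltage series for a set of candidate stoichiometries.

    Each candidate's reversal potential under ``cond`` becomes a target
    voltage, and the external K+ needed to clamp it (for the stated internal
    K+) is computed from the Nernst relation.  Entries are sorted by voltage.
    """
    if len(candidates) == 0:
        raise InvalidInputError("candidates must be non-empty")
    k = cond.k_in if k_in is None else k_in
    entries = []
    for cand in candidates:
        target = reversal_potential(cond, cand, consts)
        entries.append(
            VoltagePlanEntry(cand, target, required_k_out(target, k, consts))
        )
    return sorted(entries, key=lambda e: e.target_voltage)


def _check_call_consistency(
    calls: Sequence[tuple[float, FluxCall]]
) -> None:
    """Acidification requires V below the reversal, alkalinization above, so
    every acidification voltage must lie below every alkalinization
    voltage."""
    acids = [v for v, c in calls if c.direction == FluxDirection.ACIDIFICATION]
    alks = [v for v, c in calls if c.direction == FluxDirection.ALKALINIZATION]
    if acids and alks and max(acids) >= min(alks):
        raise InconsistentCallsError(
            f"acidification at {max(acids)} mV is not below alkalinization "
            f"at {min(alks)} mV: direction must be monotone in voltage"
        )


def infer_stoichiometry(
    calls: Sequence[tuple[float, FluxCall]],
    cond: AssayConditions,
    candidates: Iterable[int] = DEFAULT_CANDIDATES,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
    match_tol_mv: float = 2.0,
) -> StoichiometryEstimate:
    """Bracket the proton count n from flux calls at clamped voltages.

    ``calls`` pairs each applied voltage (mV) with its :class:`FluxCall`.
    A candidate n is direction-consistent when its reversal potential lies
    strictly above every acidification voltage and strictly below every
    alkalinization voltage.  Among the direction-consistent candidates,
    those whose reversal potential falls within ``match_tol_mv`` of a
    no-net-flux voltage are point matches; a unique match fixes ``point_n``.
    The returned bracket spans the direction-consistent set, and
    ``ambiguous`` is set whenever more than one candidate survives or no
    point estimate exists.
    """
    calls = list(calls)
    if len(calls) == 0:
        raise InvalidInputError("at least one flux call is required")
    _check_call_consistency(calls)

    cand_list = sorted(set(int(n) for n in candidates))
    if not cand_list or cand_list[0] < 1:
        raise InvalidInputError("candidates must be integers >= 1")

    rev = {n: reversal_potential(cond, Stoichiometry(n), consts) for n in cand_list}

    consistent = []
    for n in cand_list:
        ok = True
        for v, call in calls:
            if call.direction == FluxDirection.ACIDIFICATION and not rev[n] > v:
                ok = False
                break
            if call.direction == FluxDirection.ALKALINIZATION and not rev[n] < v:
                ok = False
                break
        if ok:
            consistent.append(n)

    if not consistent:
        return StoichiometryEstimate(None, None, None, ambiguous=True)

    nnf_voltages = [v for v, c in calls if c.direction == FluxDirection.NO_NET_FLUX]
    matches = [
        n
        for n in consistent
        if any(abs(rev[n] - v) <= match_tol_mv for v in nnf_voltages)
    ]
    point = matches[0] if len(matches) == 1 else None

    lower, upper = consistent[0], consistent[-1]
    ambiguous = point is None or lower != upper
    return StoichiometryEstimate(lower, upper, point, ambiguous)


# ---------------------------------------------------------------------------
# End-to-end parameter-recovery harness
# ---------------------------------------------------------------------------

@dataclass
class RecoveryReport:
    """Outcome of a seeded Monte-Carlo recovery experiment."""

    true_n: int
    n_runs: int
    n_recovered: int
    n_point_correct: int
    n_ambiguous: int
    estimates: list[StoichiometryEstimate]

    @property
    def recovery_fraction(self) -> float:
        return self.n_recovered / self.n_runs

    @property
    def ambiguous_fraction(self) -> float:
        return self.n_ambiguous / self.n_runs


def _derive_seed(seed: int, index: int) -> int:
    return int(np.random.SeedSequence([seed, index]).generate_state(1)[0] % (2**31))


def end_to_end_recovery(
    substrate: SubstrateSpec,
    cond: AssayConditions,
    liposome: LiposomeParams = LiposomeParams(),
    seeds: Sequence[int] = tuple(range(100)),
    candidates: Sequence[Stoichiometry] | None = None,
    infer_candidates: Iterable[int] = DEFAULT_CANDIDATES,
    n_replicates: int = 3,
    noise_sd: float = 0.01,
    valinomycin_time: float = 10.0,
    duration: float = 70.0,
    sample_interval: float = 0.5,
    window: tuple[float, float] = DEFAULT_WINDOW,
    k_sigma: float = 2.0,
    consts: ThermoConstants = DEFAULT_CONSTANTS,
) -> RecoveryReport:
    """Full pipeline round trip: design, simulate, process, classify, infer.

    The substrate's own stoichiometry is the ground truth.  For each seed,
    the designed voltage series (one clamped voltage per candidate; by
    default the true n and its two neighbours) is simulated with
    ``n_replicates`` noisy replicates per voltage, traces are reduced to
    normalized window statistics, flux directions are classified against the
    pooled baseline noise, and the stoichiometry estimate is computed.  A
    run counts as recovered when the estimate's bracket contains the true n.
    """
    true_n = substrate.stoichiometry.n_protons
    if candidates is None:
        lo = max(1, true_n - 1)
        candidates = tuple(Stoichiometry(n) for n in (lo, true_n, true_n + 1))
    plan = design_voltage_series(cond, candidates, consts=consts)

    estimates = []
    n_recovered = n_point = n_ambig = 0
    for seed in seeds:
        calls = []
        for j, entry in enumerate(plan):
            proto = AssayProtocol(
                conditions=AssayConditions(
                    ph_in=cond.ph_in,
                    ph_out=cond.ph_out,
                    pep_in=cond.pep_in,
                    pep_out=cond.pep_out,
                    k_in=cond.k_in,
                    k_out=entry.k_out_required,
                ),
                substrate=substrate,
                events=(AssayEvent(valinomycin_time, "valinomycin"),),
                duration=duration,
                sample_interval=sample_interval,
                noise_sd=noise_sd,
                seed=_derive_seed(int(seed), j),
            )
            traces = simulate_replicates(proto, liposome, n_replicates, consts)
            ratios = [normalize(compute_ratio(tr)) for tr in traces]
            baseline = np.concatenate(
                [r.f_r[r.time < valinomycin_time] for r in ratios]
            )
            # floor keeps the classifier defined in the noise-free limit
            baseline_sd = max(float(np.std(baseline, ddof=1)), 1e-9)
            stat = window_stats(ratios, window)
            calls.append(
                (entry.target_voltage, classify_flux(stat, baseline_sd, k_sigma))
            )
        est = infer_stoichiometry(calls, cond, infer_candidates, consts)
        estimates.append(est)
        if est.contains(true_n):
            n_recovered += 1
        if est.point_n == true_n:
            n_point += 1
        if est.ambiguous:
            n_ambig += 1

    return RecoveryReport(
        true_n=true_n,
        n_runs=len(list(seeds)),
        n_recovered=n_recovered,
        n_point_correct=n_point,
        n_ambiguous=n_ambig,
        estimates=estimates,
    )
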