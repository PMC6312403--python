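"""Layered-cytosol model of biosensor membrane translocation.

A soluble fluorescent biosensor (e.g. a PH-domain lipid probe) distributes
uniformly through the evanescent field at rest: ``m`` molecules in each of
the ``N`` layers of a :class:`~tirfquant.optics.LayerGrid`, each layer
illuminated with relative intensity ``I_i``.  The recorded baseline
fluorescence is

    F_initial = B * sum_i m * I_i

and time traces are normalized so that ``F_initial = 1`` (which also fixes
the per-molecule brightness ``B`` to play no role in any ratio).

Upon stimulation, ``delta_m`` molecules move to the membrane layer
(``i = 0``).  Two redistribution scenarios bracket where they come from:

``fixed_total``
    The total number of molecules in the field is fixed; the recruited
    molecules are drawn evenly from all ``N`` layers:

        F = B * [ delta_m * I_0 + sum_i (m - delta_m/N) * I_i ]

``fixed_cytosol``
    Cytosolic layer occupancies stay at ``m``; recruited molecules are
    simply added to the membrane layer:

        F = B * [ (m + delta_m) * I_0 + sum_{i>=1} m * I_i ]

Both equations are affine in ``delta_m``, so the inversion from a measured
fold-change ``F`` is closed-form.  The headline output is the membrane
ratio

    R_m = (m + delta_m) / m,

the fold-increase in membrane-layer molecules, which is independent of both
``B`` and the cell's absolute baseline brightness.  Because most of the
TIRF signal originates from the cytosolic layers, ``R_m`` is much larger
than the raw fold-change ``F``: a modest ~1.5-fold total-signal increase
corresponds to roughly ten-fold more membrane-bound probe.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .optics import LayerGrid

__all__ = [
    "FIXED_TOTAL",
    "FIXED_CYTOSOL",
    "SCENARIOS",
    "RestingState",
    "TranslocationEstimate",
    "solve_resting_density",
    "solve_delta_m",
    "membrane_ratio",
    "forward_fold_change",
    "max_fold_change",
    "estimate_translocation",
    "fold_change_curve",
]

#: Redistribution scenario: recruited molecules drawn evenly from all layers
#: of a fixed total pool.
FIXED_TOTAL = "fixed_total"
#: Redistribution scenario: cytosolic layers unchanged, molecules added to
#: the membrane layer.
FIXED_CYTOSOL = "fixed_cytosol"

SCENARIOS = (FIXED_TOTAL, FIXED_CYTOSOL)


def _check_scenario(scenario: str) -> None:
    if scenario not in SCENARIOS:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of {SCENARIOS}")


@dataclass(frozen=True)
class RestingState:
    """Resting (pre-stimulus) distribution of the biosensor.

    Attributes
    ----------
    molecules_per_layer : float
        ``m``, the number of molecules per layer at rest, in the units fixed
        by the ``F_initial = 1`` normalization.
    grid : LayerGrid
        The discretized illumination profile.
    brightness : float
        Per-molecule emission ``B``.  Under the standard normalization this
        is 1; it is exposed only to verify that ratios are independent of it.
    """

    molecules_per_layer: float
    grid: LayerGrid
    brightness: float = 1.0

    def __post_init__(self) -> None:
        if self.molecules_per_layer <= 0:
            raise ValueError("molecules_per_layer must be positive")
        if self.brightness <= 0:
            raise ValueError("brightness must be positive")

    @property
    def initial_fluorescence(self) -> float:
        """``F_initial = B * m * Sigma I`` (1 when solved by normalization)."""
        return (
            self.brightness * self.molecules_per_layer * self.grid.total_illumination
        )


def solve_resting_density(grid: LayerGrid, brightness: float = 1.0) -> RestingState:
    """Solve for the resting per-layer molecule count ``m``.

    The normalization ``F_initial = B * m * Sigma_i I_i = 1`` gives the
    closed form ``m = 1 / (B * Sigma_i I_i)``.
    """
    if brightness <= 0:
        raise ValueError("brightness must be positive")
    m = 1.0 / (brightness * grid.total_illumination)
    return RestingState(molecules_per_layer=m, grid=grid, brightness=brightness)


def max_fold_change(resting: RestingState, scenario: str = FIXED_TOTAL) -> float:
    """Largest fold-change representable under a scenario.

    In the fixed-total scenario the cytosol empties completely when
    ``delta_m = N * m``, at which point ``F = B * N * m * I_0``; larger
    fold-changes would imply negative cytosolic density.  The fixed-cytosol
    scenario adds molecules from an unmodeled reservoir and is unbounded.
    """
    _check_scenario(scenario)
    if scenario == FIXED_CYTOSOL:
        return float("inf")
    grid = resting.grid
    return (
        resting.brightness
        * grid.n_layers
        * resting.molecules_per_layer
        * float(grid.illumination[0])
    )


def forward_fold_change(
    resting: RestingState,
    delta_m: float,
    scenario: str = FIXED_TOTAL,
    allow_depletion: bool = False,
) -> float:
    """Predicted total-fluorescence fold-change for a given ``delta_m``.

    Exact affine forward map of the scenario equation; the inverse of
    :func:`solve_delta_m`.

    Parameters
    ----------
    allow_depletion
        Permit ``delta_m < 0`` (net loss of probe from the field, e.g. under
        PI3K inhibition), which the model otherwise rejects.
    """
    _check_scenario(scenario)
    if delta_m < 0 and not allow_depletion:
        raise ValueError("depletion not modeled: delta_m < 0 (pass allow_depletion=True)")
    m = resting.molecules_per_layer
    grid = resting.grid
    if scenario == FIXED_TOTAL:
        if m - delta_m / grid.n_layers < 0:
            raise ValueError(
                "implies negative cytosolic density: delta_m exceeds N*m"
            )
        total = delta_m * grid.illumination[0] + (
            m - delta_m / grid.n_layers
        ) * grid.total_illumination
    else:
        total = (m + delta_m) * grid.illumination[0] + m * (
            grid.total_illumination - grid.illumination[0]
        )
    return float(resting.brightness * total)


def solve_delta_m(
    fold_change: float,
    resting: RestingState,
    scenario: str = FIXED_TOTAL,
    allow_depletion: bool = False,
) -> float:
    """Invert a measured fold-change into the recruited molecule count.

    Closed-form solution of the affine scenario equation:

    - fixed_total:   ``delta_m = (F/B - m*SigmaI) / (I_0 - SigmaI/N)``
    - fixed_cytosol: ``delta_m = (F/B - m*SigmaI) / I_0``

    Parameters
    ----------
    fold_change
        Baseline-normalized total fluorescence after stimulation
        (``F_initial = 1`` units).
    allow_depletion
        Accept ``fold_change`` below baseline and return a negative
        ``delta_m`` with a warning, instead of raising.  The redistribution
        model is not designed for probe depletion; sub-unity cohorts (e.g.
        under kinase inhibition) are outside its intended use.

    Raises
    ------
    ValueError
        If ``fold_change`` is below the resting value (and depletion is not
        allowed), or exceeds the scenario maximum (fixed_total).
    """
    _check_scenario(scenario)
    m = resting.molecules_per_layer
    grid = resting.grid
    f_initial = resting.initial_fluorescence
    if fold_change < f_initial:
        if not allow_depletion:
            raise ValueError(
                f"depletion not modeled: fold_change {fold_change} is below the "
                f"resting value {f_initial:g} (pass allow_depletion=True to "
                "extrapolate)"
            )
        warnings.warn(
            "fold_change below baseline: extrapolating the redistribution model "
            "to delta_m < 0",
            UserWarning,
            stacklevel=2,
        )
    i0 = float(grid.illumination[0])
    sigma = grid.total_illumination
    excess = fold_change / resting.brightness - m * sigma
    if scenario == FIXED_TOTAL:
        f_max = max_fold_change(resting, scenario)
        if fold_change > f_max:
            raise ValueError(
                f"implies negative cytosolic density: fold_change {fold_change} "
                f"exceeds the fixed-total maximum {f_max:g}"
            )
        delta_m = excess / (i0 - sigma / grid.n_layers)
    else:
        delta_m = excess / i0
    return float(delta_m)


def membrane_ratio(resting: RestingState, delta_m: float) -> float:
    """Membrane ratio ``R_m = (m + delta_m) / m``.

    The fold-increase in membrane-layer molecules after stimulation.
    ``delta_m = 0`` gives 1.
    """
    return float(
        (resting.molecules_per_layer + delta_m) / resting.molecules_per_layer
    )


@dataclass(frozen=True)
class TranslocationEstimate:
    """Result of inverting one fold-change measurement.

    Attributes
    ----------
    fold_change : float
        The measured normalized fold-change ``F``.
    delta_m : float
        Molecules recruited to the membrane layer.
    membrane_ratio : float
        ``R_m = (m + delta_m)/m``.
    scenario : str
        ``"fixed_total"`` or ``"fixed_cytosol"``.
    """

    fold_change: float
    delta_m: float
    membrane_ratio: float
    scenario: str


def estimate_translocation(
    fold_change: float,
    resting: RestingState,
    scenario: str = FIXED_TOTAL,
    allow_depletion: bool = False,
) -> TranslocationEstimate:
    """Convenience wrapper: fold-change -> (delta_m, R_m) in one call."""
    delta_m = solve_delta_m(
        fold_change, resting, scenario=scenario, allow_depletion=allow_depletion
    )
    return TranslocationEstimate(
        fold_change=float(fold_change),
        delta_m=delta_m,
        membrane_ratio=membrane_ratio(resting, delta_m),
        scenario=scenario,
    )


def fold_change_curve(
    resting: RestingState,
    delta_m: np.ndarray,
    scenario: str = FIXED_TOTAL,
) -> np.ndarray:
    """Vectorized forward map for a trajectory of ``delta_m`` values.

    Used by the synthetic-data generator to turn recruitment kinetics
    ``delta_m(t)`` into a ground-truth fluorescence trajectory ``F(t)``.
    Negative values (depletion) are evaluated without range checks; the
    affine equations extrapolate smoothly.
    """
    _check_scenario(scenario)
    delta_m = np.asarray(delta_m, dtype=float)
    m = resting.molecules_per_layer
    grid = resting.grid
    i0 = float(grid.illumination[0])
    sigma = grid.total_illumination
    if scenario == FIXED_TOTAL:
        total = delta_m * i0 + (m - delta_m / grid.n_layers) * sigma
    else:
        total = (m + delta_m) * i0 + m * (sigma - i0)
    return resting.brightness * total
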