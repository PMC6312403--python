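"""Evanescent-field geometry for objective-type TIRF microscopy.

In total internal reflection fluorescence (TIRF) microscopy, excitation light
travelling through the coverslip (refractive index ``n_coverslip``) strikes
the interface with the aqueous sample (``n_solution``) at an incidence angle
above the critical angle

    theta_c = arcsin(n_solution / n_coverslip)

and is totally internally reflected.  A non-propagating *evanescent* field
leaks into the sample, with intensity decaying exponentially with distance
``h`` from the coverslip:

    I(h) = exp(-tau * h),    tau = 1 / d,

where the characteristic penetration depth is

    d = lambda0 / (4 pi n_coverslip) * (sin^2 theta - sin^2 theta_c)^(-1/2).

This module computes the geometry (:func:`critical_angle`,
:func:`penetration_depth`) and discretizes the decay over molecular layers
(:func:`illumination_profile`), the representation used by
:mod:`tirfquant.translocation` to apportion fluorescence between a
membrane-proximal layer and the cytosol above it.

Angles are degrees at every public interface; radians are internal only.
Lengths are nanometers.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "OpticalConfig",
    "EvanescentField",
    "LayerGrid",
    "critical_angle",
    "penetration_depth",
    "illumination_profile",
    "DEFAULT_LAYER_THICKNESS_NM",
    "DEFAULT_N_LAYERS",
]

logger = logging.getLogger(__name__)

#: Default layer height, nm — the approximate size of a PH-domain biosensor
#: fused to a fluorescent protein, so that the membrane plus membrane-bound
#: probe occupy the first layer.
DEFAULT_LAYER_THICKNESS_NM = 10.0

#: Default number of layers.  With a decay constant of ~0.008 nm^-1 the field
#: is negligible beyond ~500 nm, i.e. past layer index 49.
DEFAULT_N_LAYERS = 50


def critical_angle(n_solution: float, n_coverslip: float) -> float:
    """Critical angle for total internal reflection, in degrees.

    Parameters
    ----------
    n_solution
        Refractive index of the aqueous medium on the far side of the
        interface (e.g. 1.33 for saline).
    n_coverslip
        Refractive index of the incident medium (e.g. 1.53 for glass).

    Returns
    -------
    float
        ``arcsin(n_solution / n_coverslip)`` in degrees.

    Raises
    ------
    ValueError
        If ``n_solution >= n_coverslip`` (total internal reflection
        impossible: the incident medium must be optically denser), or if
        either index is non-positive.
    """
    if n_solution <= 0 or n_coverslip <= 0:
        raise ValueError("refractive indices must be positive")
    if n_solution >= n_coverslip:
        raise ValueError(
            "total internal reflection impossible: "
            f"n_solution={n_solution} >= n_coverslip={n_coverslip}"
        )
    return math.degrees(math.asin(n_solution / n_coverslip))


@dataclass(frozen=True)
class OpticalConfig:
    """Optical parameters of a TIRF illumination path.

    Attributes
    ----------
    wavelength : float
        Vacuum excitation wavelength, nm.
    n_solution : float
        Refractive index of the sample medium.
    n_coverslip : float
        Refractive index of the coverslip.
    incidence_angle : float
        Angle of incidence at the coverslip/solution interface, degrees.
    critical_angle_override : float or None
        If given, use this critical angle (degrees) instead of the one
        computed from the refractive indices.  Published setups sometimes
        quote a critical angle that does not exactly match
        ``arcsin(n_solution/n_coverslip)`` (e.g. because a slightly
        different solution index was used); the override reproduces such
        readings without silently altering the indices.
    """

    wavelength: float
    n_solution: float
    n_coverslip: float
    incidence_angle: float
    critical_angle_override: float | None = None

    def __post_init__(self) -> None:
        if self.wavelength <= 0:
            raise ValueError("wavelength must be positive")
        if not (1.0 <= self.n_solution < self.n_coverslip):
            raise ValueError(
                "require 1 <= n_solution < n_coverslip, got "
                f"n_solution={self.n_solution}, n_coverslip={self.n_coverslip}"
            )
        if not (0.0 < self.incidence_angle < 90.0):
            raise ValueError("incidence_angle must be in (0, 90) degrees")
        if self.critical_angle_override is not None and not (
            0.0 < self.critical_angle_override < 90.0
        ):
            raise ValueError("critical_angle_override must be in (0, 90) degrees")

    @property
    def critical_angle(self) -> float:
        """Critical angle in degrees (override if set, else computed)."""
        if self.critical_angle_override is not None:
            return self.critical_angle_override
        return critical_angle(self.n_solution, self.n_coverslip)


@dataclass(frozen=True)
class EvanescentField:
    """Derived evanescent-field constants.

    Attributes
    ----------
    critical_angle : float
        Critical angle used, degrees.
    depth : float
        Characteristic (1/e) penetration depth, nm.
    decay : float
        Decay constant ``tau = 1/depth``, nm^-1.
    """

    critical_angle: float
    depth: float
    decay: float

    def __post_init__(self) -> None:
        if self.depth <= 0:
            raise ValueError("depth must be positive")
        if not math.isclose(self.decay * self.depth, 1.0, rel_tol=1e-9):
            raise ValueError("decay must equal 1/depth")


def penetration_depth(config: OpticalConfig) -> EvanescentField:
    """Evanescent-field penetration depth and decay constant.

    Evaluates ``d = lambda0 / (4 pi n_coverslip) *
    (sin^2 theta - sin^2 theta_c)^(-1/2)`` for the supplied configuration.

    Raises
    ------
    ValueError
        If the incidence angle does not exceed the (possibly overridden)
        critical angle — there is then no evanescent field (at exactly the
        critical angle the formula diverges).
    """
    theta_c = config.critical_angle
    if config.incidence_angle <= theta_c:
        raise ValueError(
            "no evanescent field: sub-critical incidence "
            f"(incidence {config.incidence_angle} deg <= critical {theta_c:.4g} deg)"
        )
    sin2_theta = math.sin(math.radians(config.incidence_angle)) ** 2
    sin2_theta_c = math.sin(math.radians(theta_c)) ** 2
    depth = (
        config.wavelength
        / (4.0 * math.pi * config.n_coverslip)
        * (sin2_theta - sin2_theta_c) ** -0.5
    )
    return EvanescentField(critical_angle=theta_c, depth=depth, decay=1.0 / depth)


@dataclass(frozen=True)
class LayerGrid:
    """Discretized illumination profile over stacked molecular layers.

    Layer ``i`` spans depths ``[i*layer_thickness, (i+1)*layer_thickness)``;
    its illumination is sampled at the coverslip-proximal edge,
    ``I_i = exp(-tau * i * layer_thickness)``, so the membrane layer
    (``i = 0``) has unit illumination.

    Attributes
    ----------
    illumination : numpy.ndarray
        Relative intensities per layer, strictly positive and strictly
        decreasing, ``illumination[0] == 1``.
    layer_thickness : float
        Layer height, nm.
    """

    illumination: np.ndarray
    layer_thickness: float = DEFAULT_LAYER_THICKNESS_NM

    def __post_init__(self) -> None:
        illum = np.asarray(self.illumination, dtype=float)
        object.__setattr__(self, "illumination", illum)
        if self.layer_thickness <= 0:
            raise ValueError("invalid grid: layer_thickness must be positive")
        if illum.ndim != 1 or illum.size < 1:
            raise ValueError("invalid grid: illumination must be a non-empty vector")
        if not math.isclose(illum[0], 1.0, rel_tol=1e-12):
            raise ValueError("invalid grid: illumination[0] must equal 1")
        if np.any(illum <= 0):
            raise ValueError("invalid grid: illumination must be strictly positive")
        if illum.size > 1 and np.any(np.diff(illum) >= 0):
            raise ValueError("invalid grid: illumination must be strictly decreasing")

    @property
    def n_layers(self) -> int:
        return int(self.illumination.size)

    @property
    def total_illumination(self) -> float:
        """Sum of per-layer illumination, Sigma_i I_i."""
        return float(self.illumination.sum())

    @property
    def membrane_fraction(self) -> float:
        """Fraction of total illumination in the membrane layer, I_0 / Sigma I.

        For a uniformly distributed fluorophore this is the fraction of the
        recorded TIRF signal that originates from the membrane layer; the
        remainder is cytosolic contamination.
        """
        return float(self.illumination[0] / self.illumination.sum())

    @property
    def depths(self) -> np.ndarray:
        """Proximal-edge depth of each layer, nm."""
        return np.arange(self.n_layers) * self.layer_thickness


def illumination_profile(
    field: EvanescentField | float,
    layer_thickness: float = DEFAULT_LAYER_THICKNESS_NM,
    n_layers: int = DEFAULT_N_LAYERS,
) -> LayerGrid:
    """Discretize the evanescent decay over ``n_layers`` molecular layers.

    Parameters
    ----------
    field
        An :class:`EvanescentField`, or the decay constant ``tau`` (nm^-1)
        directly.
    layer_thickness
        Layer height, nm (default 10).
    n_layers
        Number of layers (default 50).

    Returns
    -------
    LayerGrid

    Warns
    -----
    UserWarning
        If truncating the exponential at ``n_layers`` discards more than 5%
        of the infinite-series illumination (i.e. the grid is too shallow
        for the given decay constant).
    """
    decay = field.decay if isinstance(field, EvanescentField) else float(field)
    if decay <= 0:
        raise ValueError("invalid grid: decay constant must be positive")
    if layer_thickness <= 0:
        raise ValueError("invalid grid: layer_thickness must be positive")
    if n_layers < 1:
        raise ValueError("invalid grid: n_layers must be >= 1")

    i = np.arange(n_layers)
    illumination = np.exp(-decay * i * layer_thickness)

    # Discarded fraction of the infinite geometric series is r^N.
    r = math.exp(-decay * layer_thickness)
    discarded = r**n_layers
    if discarded > 0.05:
        warnings.warn(
            f"layer grid truncates {discarded:.1%} of the total illumination "
            f"(n_layers={n_layers}, decay={decay:.4g}/nm); consider a deeper grid",
            UserWarning,
            stacklevel=2,
        )
    grid = LayerGrid(illumination=illumination, layer_thickness=layer_thickness)
    logger.info(
        "layer grid: %d layers x %.3g nm, decay %.4g/nm, membrane fraction %.3f",
        n_layers,
        layer_thickness,
        decay,
        grid.membrane_fraction,
    )
    return grid
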