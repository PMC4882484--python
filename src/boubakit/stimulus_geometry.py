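"""Radial-frequency (RF) pattern geometry.

An RF pattern is a closed contour obtained by modulating the radius of a
base circle sinusoidally as a function of polar angle::

    r(theta) = r_mean * (1 + A * m(theta))

where ``A`` is the modulation amplitude (fractional radial deviation),
``m`` is a unit-peak periodic modulator with ``frequency`` cycles per
revolution, and the *spikiness* parameter adds triangular-wave harmonics
above the fundamental so each lobe sharpens toward a spike.

The module generates single and composite RF contours, validates their
geometry (lobe counts, positivity), and renders them as SVG or PNG line
drawings (black outline on a white background).
"""

from __future__ import annotations

import functools
import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "ParameterError",
    "RFSpec",
    "CompositeSpec",
    "ContourPolyline",
    "StimulusDesign",
    "DEFAULT_FREQUENCIES",
    "DEFAULT_AMPLITUDES",
    "DEFAULT_SPIKINESS",
    "triangular_modulator",
    "radius_profile",
    "composite_radius",
    "composite_preset",
    "sample_contour",
    "count_lobes",
    "render_shape",
    "render_design",
]


class ParameterError(ValueError):
    """Raised when a stimulus parameter violates its allowed range."""


#: Factor levels of the default 6 x 4 x 3 factorial stimulus design.
DEFAULT_FREQUENCIES = (4, 5, 6, 7, 8, 9)
DEFAULT_AMPLITUDES = (0.1, 0.2, 0.3, 0.4)
DEFAULT_SPIKINESS = (0, 1, 30)


@dataclass(frozen=True)
class RFSpec:
    """Parameters of one radial-frequency pattern.

    Parameters
    ----------
    frequency
        Number of modulation cycles per revolution (integer >= 1).
    amplitude
        Fractional radial deviation ``A`` in [0, 1].
    spikiness
        Number of triangular-wave harmonics added above the fundamental
        (integer >= 0; 0 gives a pure sinusoid).
    phase
        Phase of the modulator, radians.
    r_mean
        Base-circle radius (> 0, arbitrary length units).
    """

    frequency: int
    amplitude: float
    spikiness: int = 0
    phase: float = 0.0
    r_mean: float = 1.0

    def __post_init__(self) -> None:
        if not float(self.frequency).is_integer() or self.frequency < 1:
            raise ParameterError(f"frequency must be an integer >= 1, got {self.frequency}")
        if not 0.0 <= self.amplitude <= 1.0:
            raise ParameterError(f"amplitude must lie in [0, 1], got {self.amplitude}")
        if not float(self.spikiness).is_integer() or self.spikiness < 0:
            raise ParameterError(f"spikiness must be an integer >= 0, got {self.spikiness}")
        if self.r_mean <= 0:
            raise ParameterError(f"r_mean must be > 0, got {self.r_mean}")


@dataclass(frozen=True)
class CompositeSpec:
    """A linear combination of sinusoidal RF components sharing one base circle.

    ``components`` is an ordered tuple of ``(frequency, amplitude, phase)``
    triples; the radius is ``r_mean * (1 + sum_i A_i sin(w_i theta + phi_i))``.
    """

    components: tuple[tuple[int, float, float], ...]
    r_mean: float = 1.0

    def __post_init__(self) -> None:
        if not self.components:
            raise ParameterError("composite needs at least one component")
        if self.r_mean <= 0:
            raise ParameterError(f"r_mean must be > 0, got {self.r_mean}")
        for w, a, _ in self.components:
            if w < 1 or not float(w).is_integer():
                raise ParameterError(f"component frequency must be integer >= 1, got {w}")
            if a < 0:
                raise ParameterError(f"component amplitude must be >= 0, got {a}")
        if sum(a for _, a, _ in self.components) >= 1.0:
            # Worst-case deviation; guarantees a strictly positive radius.
            raise ParameterError("summed component amplitudes must stay below 1")


@dataclass(frozen=True)
class ContourPolyline:
    """Ordered (x, y) vertices of a sampled closed contour."""

    vertices: np.ndarray
    closed: bool = True

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2:
            raise ParameterError("vertices must be an (n, 2) array")
        object.__setattr__(self, "vertices", v)
        if self.closed and not np.allclose(v[0], v[-1]):
            raise ParameterError("closed contour must end on its first vertex")


@dataclass(frozen=True)
class StimulusDesign:
    """Factorial crossing of frequency x amplitude x spikiness levels."""

    frequency_levels: tuple[int, ...] = DEFAULT_FREQUENCIES
    amplitude_levels: tuple[float, ...] = DEFAULT_AMPLITUDES
    spikiness_levels: tuple[int, ...] = DEFAULT_SPIKINESS
    include_controls: bool = False

    def conditions(self) -> list[tuple[int, float, int]]:
        """All (frequency, amplitude, spikiness) conditions in factorial order."""
        return list(
            itertools.product(
                self.frequency_levels, self.amplitude_levels, self.spikiness_levels
            )
        )

    def __len__(self) -> int:
        return (
            len(self.frequency_levels)
            * len(self.amplitude_levels)
            * len(self.spikiness_levels)
        )

    def specs(self) -> list[RFSpec]:
        return [RFSpec(f, a, s) for f, a, s in self.conditions()]


# ---------------------------------------------------------------------------
# modulator


def _triangle_partial_sum(x: np.ndarray, spikiness: int) -> np.ndarray:
    """Truncated triangle-wave Fourier series: fundamental + `spikiness` harmonics.

    sin(x) - sin(3x)/9 + sin(5x)/25 - ... (odd harmonics, 1/n^2 amplitudes,
    alternating sign), truncated after ``spikiness`` terms beyond the fundamental.
    """
    out = np.sin(x)
    for j in range(1, spikiness + 1):
        n = 2 * j + 1
        out += ((-1) ** j) * np.sin(n * x) / n**2
    return out


@functools.lru_cache(maxsize=None)
def _peak_value(spikiness: int) -> float:
    """Max over one period of the truncated triangle series, to ~machine precision."""
    if spikiness == 0:
        return 1.0
    from scipy.optimize import minimize_scalar

    grid = np.linspace(0.0, 2.0 * np.pi, 1 << 16, endpoint=False)
    vals = _triangle_partial_sum(grid, spikiness)
    i = int(np.argmax(vals))
    h = grid[1] - grid[0]
    res = minimize_scalar(
        lambda x: -_triangle_partial_sum(np.asarray(x), spikiness),
        bounds=(grid[i] - h, grid[i] + h),
        method="bounded",
        options={"xatol": 1e-12},
    )
    return float(max(vals[i], -res.fun))


def triangular_modulator(
    frequency: int,
    phase: float,
    spikiness: int,
    theta: float | np.ndarray,
    normalize: bool = True,
):
    """Unit-peak periodic modulator: fundamental sinusoid plus triangle harmonics.

    With ``spikiness = 0`` this is ``sin(frequency * theta + phase)``; each
    additional harmonic is the next odd term of the triangle-wave Fourier
    series (amplitude 1/n^2, alternating sign), so large ``spikiness``
    approaches an ideal triangle wave. When ``normalize`` is true the
    waveform is rescaled to unit peak so the stimulus amplitude factor
    always equals the maximum fractional radial deviation.
    """
    if not float(frequency).is_integer() or frequency < 1:
        raise ParameterError(f"frequency must be an integer >= 1, got {frequency}")
    if not float(spikiness).is_integer() or spikiness < 0:
        raise ParameterError(f"spikiness must be an integer >= 0, got {spikiness}")
    x = np.asarray(theta, dtype=float) * frequency + phase
    out = _triangle_partial_sum(x, int(spikiness))
    if normalize and spikiness > 0:
        out = out / _peak_value(int(spikiness))
    if np.isscalar(theta):
        return float(out)
    return out


def radius_profile(spec: RFSpec, theta: float | np.ndarray):
    """Radius of the RF contour at polar angle(s) ``theta``."""
    m = triangular_modulator(spec.frequency, spec.phase, spec.spikiness, theta)
    return spec.r_mean * (1.0 + spec.amplitude * m)


def composite_radius(spec: CompositeSpec, theta: float | np.ndarray):
    """Radius of a composite contour: base circle plus summed sinusoids."""
    th = np.asarray(theta, dtype=float)
    dev = np.zeros_like(th)
    for w, a, phi in spec.components:
        dev += a * np.sin(w * th + phi)
    r = spec.r_mean * (1.0 + dev)
    if np.any(r <= 0):
        raise ParameterError("composite radius is not strictly positive")
    if np.isscalar(theta):
        return float(r)
    return r


#: Component frequencies / amplitudes of the five-harmonic composite shapes.
_COMPOSITE_FREQS = (7, 14, 21, 28, 35)
_COMPOSITE_AMPS = (0.4, 0.2, 0.1, 0.05, 0.025)
#: Polar angle at which the aligned peaks/troughs sit (top of the figure).
_COMPOSITE_PEAK_ANGLE = np.pi / 2


def composite_preset(name: str, r_mean: float = 1.0) -> CompositeSpec:
    """Named five-component composites approximating classic Bouba/Kiki blobs.

    ``"angular"`` aligns the peaks of all five components at one angle,
    producing sharp spikes; ``"rounded"`` aligns the troughs of the 2nd and
    4th components with the peaks of the others, producing smooth bulges.
    """
    if name not in {"angular", "rounded"}:
        raise ParameterError(f"unknown composite preset {name!r}")
    comps = []
    for i, (w, a) in enumerate(zip(_COMPOSITE_FREQS, _COMPOSITE_AMPS)):
        trough = name == "rounded" and i in (1, 3)
        target = -np.pi / 2 if trough else np.pi / 2
        phi = float((target - w * _COMPOSITE_PEAK_ANGLE) % (2 * np.pi))
        comps.append((w, a, phi))
    return CompositeSpec(components=tuple(comps), r_mean=r_mean)


# ---------------------------------------------------------------------------
# sampling and validation


def _radius_at(spec: RFSpec | CompositeSpec, theta: np.ndarray) -> np.ndarray:
    if isinstance(spec, RFSpec):
        return np.asarray(radius_profile(spec, theta))
    return np.asarray(composite_radius(spec, theta))


def sample_contour(spec: RFSpec | CompositeSpec, n_points: int = 4096) -> ContourPolyline:
    """Sample the contour on a uniform theta grid and close the polygon.

    ``n_points`` distinct vertices are placed on the half-open grid
    [0, 2*pi); the first vertex is repeated at the end to close the curve.
    """
    if n_points < 16:
        raise ParameterError(f"n_points must be >= 16, got {n_points}")
    theta = np.linspace(0.0, 2.0 * np.pi, n_points, endpoint=False)
    r = _radius_at(spec, theta)
    if np.any(r <= 0):
        raise ParameterError("radius profile is not strictly positive")
    xy = np.column_stack((r * np.cos(theta), r * np.sin(theta)))
    xy = np.vstack([xy, xy[:1]])
    return ContourPolyline(vertices=xy, closed=True)


def count_lobes(contour: ContourPolyline, rtol: float = 1e-9) -> int:
    """Number of strict local maxima of radius vs angle (circular, plateau-safe).

    The contour must enclose the origin (all radii strictly positive); for an
    RF pattern the count equals the pattern's radial frequency, and a circle
    has zero lobes. Radius differences below ``rtol`` (relative to the mean
    radius) are treated as plateaus, absorbing floating-point jitter.
    """
    v = contour.vertices
    if contour.closed:
        v = v[:-1]
    r = np.hypot(v[:, 0], v[:, 1])
    if np.any(r <= 0):
        raise ParameterError("contour does not enclose the origin")
    # Quantise so sub-tolerance wiggle collapses into plateaus.
    r = np.round(r / (rtol * float(np.mean(r))))
    keep = np.concatenate(([True], np.diff(r) != 0))
    rr = r[keep]
    if rr.size and rr[0] == rr[-1]:
        rr = rr[:-1]
    if rr.size < 3:
        return 0
    prev = np.roll(rr, 1)
    nxt = np.roll(rr, -1)
    return int(np.sum((rr > prev) & (rr > nxt)))


# ---------------------------------------------------------------------------
# rendering


def _fit_transform(vertices: np.ndarray, canvas_px: int, stroke_px: int):
    """Scale/centre contour into canvas pixels, flipping to image y-down."""
    max_r = float(np.max(np.hypot(vertices[:, 0], vertices[:, 1])))
    margin = stroke_px + max(2, canvas_px // 32)
    scale = (canvas_px / 2.0 - margin) / max_r
    if scale <= 0:
        raise ParameterError("canvas too small for contour plus stroke")
    cx = cy = canvas_px / 2.0
    x = cx + vertices[:, 0] * scale
    y = cy - vertices[:, 1] * scale
    return x, y


def render_shape(
    contour: ContourPolyline,
    canvas_px: int = 512,
    stroke_px: int = 3,
    path: str | Path = "shape.png",
) -> Path:
    """Write the contour as a black outline on white, SVG or PNG by extension.

    Output bytes are deterministic for identical inputs.
    """
    path = Path(path)
    x, y = _fit_transform(contour.vertices, canvas_px, stroke_px)
    if path.suffix.lower() == ".svg":
        pts = " ".join(f"{xi:.3f},{yi:.3f}" for xi, yi in zip(x, y))
        svg = (
            '<?xml version="1.0" encoding="UTF-8"?>\n'
            f'<svg xmlns="http://www.w3.org/2000/svg" width="{canvas_px}" '
            f'height="{canvas_px}" viewBox="0 0 {canvas_px} {canvas_px}">\n'
            f'<rect width="{canvas_px}" height="{canvas_px}" fill="white"/>\n'
            f'<polyline points="{pts}" fill="none" stroke="black" '
            f'stroke-width="{stroke_px}" stroke-linejoin="round"/>\n'
            "</svg>\n"
        )
        path.write_text(svg, encoding="utf-8")
    elif path.suffix.lower() == ".png":
        from PIL import Image, ImageDraw

        img = Image.new("L", (canvas_px, canvas_px), 255)
        draw = ImageDraw.Draw(img)
        draw.line(list(zip(x, y)), fill=0, width=stroke_px, joint="curve")
        img.save(path, format="PNG", optimize=False)
    else:
        raise ParameterError(f"unsupported output format {path.suffix!r}")
    return path


def condition_stem(frequency: int, amplitude: float, spikiness: int) -> str:
    """Canonical file stem for one design condition."""
    return f"rf_F{frequency}_A{amplitude:g}_S{spikiness}"


def render_design(
    design: StimulusDesign,
    out_dir: str | Path,
    fmt: str = "svg",
    canvas_px: int = 512,
    stroke_px: int = 3,
    n_points: int = 4096,
) -> list[Path]:
    """Render every condition of the design grid (plus optional composites)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written = []
    for f, a, s in design.conditions():
        contour = sample_contour(RFSpec(f, a, s), n_points)
        written.append(
            render_shape(contour, canvas_px, stroke_px, out_dir / f"{condition_stem(f, a, s)}.{fmt}")
        )
    if design.include_controls:
        for name in ("rounded", "angular"):
            contour = sample_contour(composite_preset(name), n_points)
            written.append(
                render_shape(contour, canvas_px, stroke_px, out_dir / f"composite_{name}.{fmt}")
            )
    return written
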