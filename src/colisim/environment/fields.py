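"""Diffusing 2D molecular fields and agent local-environment coupling.

Concentrations live on an n_x x n_y grid of square bins (mM). Diffusion
uses a flux-form explicit scheme with no-flux boundaries, which conserves
total moles to machine precision. Each agent's local environment is the
single bin containing its centroid; uptake and secretion are applied to
that bin, with uptake floored at the bin's available content.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AVOGADRO = 6.02214076e23


class FieldError(Exception):
    pass


@dataclass
class Field:
    """Concentration grids per molecular species over a shared geometry."""

    bounds: tuple[float, float]  # um
    n_bins: tuple[int, int]
    concentrations: dict[str, np.ndarray] = field(default_factory=dict)
    diffusion: dict[str, float] = field(default_factory=dict)  # um^2/s
    depth: float = 1.0  # um; bins are bin_size^2 x depth volumes

    def __post_init__(self):
        for name, grid in self.concentrations.items():
            self.concentrations[name] = np.asarray(grid, dtype=float)
            if self.concentrations[name].shape != tuple(self.n_bins):
                raise FieldError(f"grid {name!r} does not match n_bins")
            if (self.concentrations[name] < 0).any():
                raise FieldError(f"negative concentrations in {name!r}")

    @property
    def bin_size(self) -> tuple[float, float]:
        return (self.bounds[0] / self.n_bins[0], self.bounds[1] / self.n_bins[1])

    @property
    def bin_volume_l(self) -> float:
        """Bin volume in liters (um^3 -> L is 1e-15)."""
        bx, by = self.bin_size
        return bx * by * self.depth * 1e-15

    def bin_of(self, location) -> tuple[int, int]:
        x, y = location
        bx, by = self.bin_size
        i = int(np.clip(x // bx, 0, self.n_bins[0] - 1))
        j = int(np.clip(y // by, 0, self.n_bins[1] - 1))
        if not (0 <= x <= self.bounds[0] and 0 <= y <= self.bounds[1]):
            raise FieldError(f"agent at {location} outside all bins")
        return i, j

    def total_mmol(self, species: str) -> float:
        return float(self.concentrations[species].sum() * self.bin_volume_l)


def diffuse_field(fld: Field, dt: float) -> Field:
    """One explicit diffusion step (in place); no-flux boundaries.

    Requires D*dt/h^2 <= 0.25 for each species (explicit stability).
    """
    bx, by = fld.bin_size
    for species, grid in fld.concentrations.items():
        d = fld.diffusion.get(species, 0.0)
        if d == 0.0:
            continue
        alpha = d * dt / min(bx, by) ** 2
        if alpha > 0.25 + 1e-12:
            raise FieldError(
                f"diffusion step unstable for {species!r}: D*dt/h^2 = {alpha:.3f} > 0.25"
            )
        fx = d * dt / bx**2 * np.diff(grid, axis=0)  # flux between rows
        grid[:-1, :] += fx
        grid[1:, :] -= fx
        fy = d * dt / by**2 * np.diff(grid, axis=1)
        grid[:, :-1] += fy
        grid[:, 1:] -= fy
    return fld


def agent_field_exchange(
    fld: Field,
    locations: list,
    exchanges: list[dict[str, float]],
) -> tuple[Field, list[dict[str, float]], list[dict[str, float]]]:
    """Apply per-agent uptake/secretion (mmol; uptake negative) to bins.

    Returns (field, per-agent local concentrations after exchange,
    per-agent shortfalls). Uptake beyond a bin's content is truncated:
    the bin is floored at zero and the unmet amount reported back so the
    caller can reconcile its internal accounting.
    """
    vol = fld.bin_volume_l
    locals_out: list[dict[str, float]] = []
    shortfalls: list[dict[str, float]] = []
    bins = [fld.bin_of(loc) for loc in locations]
    for (i, j), exchange in zip(bins, exchanges):
        short: dict[str, float] = {}
        for species, mmol in exchange.items():
            grid = fld.concentrations[species]
            delta = mmol / vol  # mM
            new = grid[i, j] + delta
            if new < 0:
                short[species] = -new * vol  # mmol that could not be taken
                new = 0.0
            grid[i, j] = new
        shortfalls.append(short)
    for (i, j) in bins:
        locals_out.append(
            {species: float(grid[i, j]) for species, grid in fld.concentrations.items()}
        )
    return fld, locals_out, shortfalls


def make_gradient_field(
    shape: str,
    bounds: tuple[float, float],
    n_bins: tuple[int, int],
    species: str = "MeAsp",
    base_concentration: float = 1.0,
    length_scale: float = float("inf"),
    origin_y: float = 0.0,
    diffusion: float = 0.0,
    depth: float = 1.0,
) -> Field:
    """Build a uniform or exponential attractant field.

    ``exponential``: c(x, y) = c0 * exp((y - y0) / lambda); the uniform
    field is the lambda -> infinity limit.
    """
    if base_concentration < 0:
        raise FieldError("base concentration must be >= 0")
    if shape not in ("uniform", "exponential"):
        raise FieldError(f"unknown field shape {shape!r}")
    nx, ny = n_bins
    by = bounds[1] / ny
    y_centers = (np.arange(ny) + 0.5) * by
    if shape == "uniform" or np.isinf(length_scale):
        grid = np.full((nx, ny), base_concentration, dtype=float)
    else:
        profile = base_concentration * np.exp((y_centers - origin_y) / length_scale)
        grid = np.tile(profile, (nx, 1))
    return Field(
        bounds=bounds,
        n_bins=n_bins,
        concentrations={species: grid},
        diffusion={species: diffusion},
        depth=depth,
    )
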