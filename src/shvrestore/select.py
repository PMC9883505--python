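"""Automatic selection of the smoothing weight by the minimax principle.

With intensities normalized to [0, 1], the energy is rewritten on the
balance parameterization ``lam_prime = 1 / (1 + lam)`` in (0, 1)::

    E_lp(f, u) = lp * F(f, u; h) + (1 - lp) * R_rho(u)

The selected weight is the saddle point ``max_lp min_u E_lp(f, u)``: each
candidate ``lp`` is scored by restoring the image (or a ROI) with
``lam = (1 - lp) / lp`` and evaluating ``E_lp`` at the minimizer.  The
profile ``lp -> E_lp(f, u*)`` is concave with a unique maximum
(Gennert-Yuille), so a hill climb from the default ``lp = 1/2`` along a
small grid finds it with few restorations.  The 3x3 preview matrix shows
the restoration at the selected smoothness and its grid neighbours
against the three sparsity presets.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .noise import quadratic_fidelity
from .solver import RegularizationParams, SolverConfig, restore, shv_value

__all__ = [
    "LambdaGrid",
    "MinimaxResult",
    "PreviewMatrix",
    "scaled_energy",
    "select_lambda",
    "preview_matrix",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LambdaGrid:
    """Strictly increasing lam_prime candidates with 1/2 in the middle.

    The default nine-point grid 0.1 ... 0.9 resolves optima to one decimal,
    which is enough because neighbouring restorations are visually close.
    """

    values: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9)

    def __post_init__(self) -> None:
        v = tuple(float(x) for x in self.values)
        if any(not 0.0 < x < 1.0 for x in v):
            raise ValueError("all lam_prime values must lie in the open interval (0, 1)")
        if any(b <= a for a, b in zip(v, v[1:])):
            raise ValueError("lam_prime values must be strictly increasing")
        if abs(v[len(v) // 2] - 0.5) > 1e-12:
            raise ValueError("the middle grid value must be 1/2")
        object.__setattr__(self, "values", v)

    @property
    def M(self) -> int:
        return len(self.values)

    @property
    def middle_index(self) -> int:
        return len(self.values) // 2


@dataclass
class MinimaxResult:
    """Outcome of the minimax search."""

    lambda_prime_star: float
    energy_profile: list[tuple[float, float]]
    restored_roi: np.ndarray
    unimodal: bool = True
    n_restorations: int = 0

    @property
    def lam_star(self) -> float:
        return (1.0 - self.lambda_prime_star) / self.lambda_prime_star


def scaled_energy(f: np.ndarray, u: np.ndarray, psf, rho: float, lambda_prime: float) -> float:
    """Balance-parameterized energy ``lp * F + (1 - lp) * R_rho``."""
    if not 0.0 < lambda_prime < 1.0:
        raise ValueError(f"lambda_prime must lie in (0, 1), got {lambda_prime}")
    return lambda_prime * quadratic_fidelity(f, u, psf) + (1.0 - lambda_prime) * shv_value(u, rho)


def _profile_is_unimodal(energies: list[float]) -> bool:
    """Single interior maximum: increases then decreases (ties tolerated)."""
    k = int(np.argmax(energies))
    rising = all(a <= b + 1e-12 for a, b in zip(energies[: k + 1], energies[1 : k + 1]))
    falling = all(a >= b - 1e-12 for a, b in zip(energies[k:], energies[k + 1 :]))
    return rising and falling


def select_lambda(
    f_roi: np.ndarray,
    psf,
    rho: float,
    grid: LambdaGrid | None = None,
    config: SolverConfig | None = None,
    search: str = "hill",
) -> MinimaxResult:
    """Select lam_prime maximizing ``E_lp(f, u*)`` over the grid.

    ``search="hill"`` restores at the middle value and both neighbours,
    moves toward the higher energy, and stops at the first decrease (then
    verifies unimodality on any remaining grid points, falling back to the
    global grid argmax if the profile is not unimodal).
    ``search="exhaustive"`` restores at every grid value.  Each candidate
    evaluation is a full restoration with the same solver configuration so
    energies are comparable.  Ties pick the smaller lam_prime (the
    smoother image).
    """
    f_roi = np.asarray(f_roi, dtype=np.float64)
    if f_roi.size == 0 or float(np.ptp(f_roi)) == 0.0:
        raise ValueError("ROI is constant or empty; select a region containing signal")
    grid = grid if grid is not None else LambdaGrid()
    cfg = config if config is not None else SolverConfig()

    cache: dict[int, tuple[float, np.ndarray]] = {}

    def evaluate(idx: int) -> float:
        if idx not in cache:
            lp = grid.values[idx]
            params = RegularizationParams.from_lam_prime(rho, lp)
            u, _ = restore(f_roi, psf, params, cfg)
            cache[idx] = (scaled_energy(f_roi, u, psf, rho, lp), u)
        return cache[idx][0]

    if search == "exhaustive":
        for i in range(grid.M):
            evaluate(i)
    elif search == "hill":
        i = grid.middle_index
        evaluate(i)
        left = evaluate(i - 1) if i - 1 >= 0 else -np.inf
        right = evaluate(i + 1) if i + 1 < grid.M else -np.inf
        step = -1 if left >= right else 1  # tie -> smaller lam_prime
        while True:
            nxt = i + step
            if nxt < 0 or nxt >= grid.M:
                break
            if evaluate(nxt) > evaluate(i):
                i = nxt
            else:
                break
    else:
        raise ValueError(f"unknown search mode {search!r}")

    visited = sorted(cache)
    energies = [cache[i][0] for i in visited]
    # argmax with smaller lam_prime preferred on ties
    best_pos = max(range(len(visited)), key=lambda p: (energies[p], -visited[p]))
    best_idx = visited[best_pos]

    unimodal = True
    if search == "hill":
        # exhaustive check mode: score the remaining grid points too
        for i in range(grid.M):
            evaluate(i)
        full = [cache[i][0] for i in range(grid.M)]
        unimodal = _profile_is_unimodal(full)
        best_idx = max(range(grid.M), key=lambda p: (full[p], -p))
        profile = list(zip(grid.values, full))
    else:
        full = energies
        unimodal = _profile_is_unimodal(full)
        profile = list(zip([grid.values[i] for i in visited], energies))

    if not unimodal:
        logger.warning(
            "scaled-energy profile over the grid is not unimodal; "
            "returning the global grid maximum"
        )

    return MinimaxResult(
        lambda_prime_star=grid.values[best_idx],
        energy_profile=profile,
        restored_roi=cache[best_idx][1],
        unimodal=unimodal,
        n_restorations=len(cache),
    )


@dataclass
class PreviewMatrix:
    """3x3 grid of candidate restorations.

    Rows vary smoothness (lam_prime), columns vary sparsity (rho); cell
    ``(i, j)`` is the restoration at ``(lambda_primes[i], rhos[j])``.
    ``default_marker`` flags cells at the default lam_prime = 1/2 and
    ``symmetric_marker`` the mirrored solution 1 - lam_prime*.
    """

    cells: list[list[np.ndarray]]
    lambda_primes: tuple[float, ...]
    rhos: tuple[float, ...]
    default_marker: list[tuple[int, int]] = field(default_factory=list)
    symmetric_marker: list[tuple[int, int]] = field(default_factory=list)

    def legend(self) -> str:
        lines = []
        for i, lp in enumerate(self.lambda_primes):
            for j, rho in enumerate(self.rhos):
                tags = []
                if (i, j) in self.default_marker:
                    tags.append("default")
                if (i, j) in self.symmetric_marker:
                    tags.append("symmetric")
                tag = f" [{', '.join(tags)}]" if tags else ""
                lines.append(f"cell ({i},{j}): lambda_prime={lp:g}, rho={rho:g}{tag}")
        return "\n".join(lines)


def preview_matrix(
    f_roi: np.ndarray,
    psf,
    smoothness_levels: tuple[float, float, float],
    sparsity_levels: tuple[float, float, float] = (0.1, 0.6, 0.9),
    config: SolverConfig | None = None,
) -> PreviewMatrix:
    """Restore a ROI at three smoothness x three sparsity settings."""
    f_roi = np.asarray(f_roi, dtype=np.float64)
    cfg = config if config is not None else SolverConfig()
    cells: list[list[np.ndarray]] = []
    for lp in smoothness_levels:
        row = []
        for rho in sparsity_levels:
            params = RegularizationParams.from_lam_prime(rho, lp)
            u, _ = restore(f_roi, psf, params, cfg)
            row.append(u)
        cells.append(row)
    pm = PreviewMatrix(
        cells=cells,
        lambda_primes=tuple(float(x) for x in smoothness_levels),
        rhos=tuple(float(x) for x in sparsity_levels),
    )
    star = smoothness_levels[len(smoothness_levels) // 2]
    for i, lp in enumerate(pm.lambda_primes):
        for j in range(len(pm.rhos)):
            if abs(lp - 0.5) < 1e-12:
                pm.default_marker.append((i, j))
            if abs(lp - (1.0 - star)) < 1e-12:
                pm.symmetric_marker.append((i, j))
    return pm
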