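"""Experiment drivers: noise and sampling-distance sweeps.

A sweep simulates one traction pattern once, perturbs the displacement
volume over a grid of noise levels and seeds (or re-samples it at varying
spacings at zero noise), reconstructs with every requested method, and
scores each reconstruction.  Results are emitted as a long-format table
(one row per method x condition x seed x metric) so the mean +/- std
summary bands are a pure aggregation step; all randomness is derived
deterministically from the config seed.

Method identifiers: ``fttc2d``, ``fttc25d``, ``direct:<scheme>`` and
``direct:<scheme>:divcorr`` with scheme one of ``2p``, ``4p``,
``patch333``.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field as dc_field
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .direct import reconstruct_direct
from .elasticity import ElasticMaterial
from .fields import DisplacementField
from .fttc import FTTCOptions, reconstruct_fttc
from .io import config_hash
from .metrics import evaluate_reconstruction, mask_from_pattern
from .results import ReconstructionResult
from .simulate import (NoiseSpec, add_noise, centered_volume_grid,
                       displacement_from_pattern, patch_traction,
                       preset_pattern)

__all__ = ["ExperimentConfig", "apply_method", "run_noise_sweep",
           "run_spacing_sweep", "summarize"]


@dataclass
class ExperimentConfig:
    """Declarative description of one sweep experiment."""

    pattern: str = "adhesion_array"
    pattern_overrides: dict = dc_field(default_factory=dict)
    nx: int = 64
    ny: int = 64
    nz: int = 9
    dx: float = 0.4
    youngs_modulus: float = 1.0e4
    poisson_ratio: float = 0.49
    noise_levels: Sequence[float] = (0.0, 0.2, 0.5, 1.0)
    spacings: Sequence[float] = (0.2, 0.4, 0.8)
    n_seeds: int = 10
    seed: int = 0
    methods: Sequence[str] = ("fttc25d", "direct:patch333")

    def __post_init__(self) -> None:
        if self.n_seeds < 1:
            raise ValueError("n_seeds must be >= 1")
        if any(n < 0 for n in self.noise_levels):
            raise ValueError("noise levels must be >= 0")
        if not self.methods:
            raise ValueError("at least one method is required")

    @property
    def material(self) -> ElasticMaterial:
        return ElasticMaterial(self.youngs_modulus, self.poisson_ratio)

    def hash(self) -> str:
        return config_hash(asdict(self))


def _derived_seed(base: int, *tags: int) -> int:
    return int(np.random.SeedSequence([base, *tags]).generate_state(1)[0]
               % (2**31))


def apply_method(method: str, u_volume: DisplacementField,
                 material: ElasticMaterial) -> ReconstructionResult:
    """Run one reconstruction method on a (possibly noisy) volume.

    FTTC variants consume the z = 0 surface layer of the volume; direct
    variants consume the full volume.
    """
    if method in ("fttc2d", "fttc25d"):
        opts = FTTCOptions(mode="2d" if method == "fttc2d" else "2.5d",
                           lambda_policy="gcv")
        return reconstruct_fttc(u_volume.surface_layer(), opts, material)
    parts = method.split(":")
    if parts[0] == "direct" and len(parts) in (2, 3):
        divcorr = len(parts) == 3
        if divcorr and parts[2] != "divcorr":
            raise ValueError(f"unknown method suffix in {method!r}")
        return reconstruct_direct(u_volume, scheme=parts[1],
                                  material=material,
                                  correct_divergence=divcorr)
    raise ValueError(f"unknown method {method!r}")


def _rows_for(report, method: str, condition_name: str, condition: float,
              seed: int, chash: str) -> list[dict]:
    return [
        {"method": method, condition_name: condition, "seed": seed,
         "metric": k, "value": v, "config_hash": chash,
         "version": __version__}
        for k, v in report.as_dict().items()
    ]


def run_noise_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Simulate -> perturb -> reconstruct -> score over noise x seed x method.

    Returns the long-format results table; aggregate with
    :func:`summarize`.  Fully deterministic given ``config.seed``.
    """
    material = config.material
    grid = centered_volume_grid(config.nx, config.ny, config.nz, config.dx)
    pattern = preset_pattern(config.pattern, **config.pattern_overrides)
    clean = displacement_from_pattern(pattern, grid, material)
    truth = patch_traction(pattern, grid.surface())
    mask = mask_from_pattern(pattern, grid.surface())
    chash = config.hash()
    rows: list[dict] = []
    for li, level in enumerate(config.noise_levels):
        for si in range(config.n_seeds):
            seed = _derived_seed(config.seed, li, si)
            noisy = add_noise(clean, NoiseSpec(level, seed)) if level > 0 \
                else clean
            for method in config.methods:
                result = apply_method(method, noisy, material)
                report = evaluate_reconstruction(result.traction, truth, mask)
                rows.extend(_rows_for(report, method, "noise", level, seed,
                                      chash))
    return pd.DataFrame(rows)


def run_spacing_sweep(config: ExperimentConfig) -> pd.DataFrame:
    """Zero-noise metrics as a function of the sampling-point distance.

    The physical field of view implied by the config (nx dx x ny dx, depth
    (nz-1) dz with dz = 2 dx) stays fixed; each spacing in
    ``config.spacings`` resamples it with the matching node counts, the
    z spacing scaling proportionally with the in-plane one.
    """
    material = config.material
    pattern = preset_pattern(config.pattern, **config.pattern_overrides)
    chash = config.hash()
    extent_x = (config.nx - 1) * config.dx
    extent_y = (config.ny - 1) * config.dx
    extent_z = (config.nz - 1) * 2.0 * config.dx
    rows: list[dict] = []
    for spacing in config.spacings:
        grid = centered_volume_grid(
            nx=int(round(extent_x / spacing)) + 1,
            ny=int(round(extent_y / spacing)) + 1,
            nz=max(int(round(extent_z / (2.0 * spacing))) + 1, 3),
            dx=spacing)
        clean = displacement_from_pattern(pattern, grid, material)
        truth = patch_traction(pattern, grid.surface())
        mask = mask_from_pattern(pattern, grid.surface())
        for method in config.methods:
            result = apply_method(method, clean, material)
            report = evaluate_reconstruction(result.traction, truth, mask)
            rows.extend(_rows_for(report, method, "spacing", spacing, 0,
                                  chash))
    return pd.DataFrame(rows)


def summarize(table: pd.DataFrame) -> pd.DataFrame:
    """Mean and standard deviation per method x condition x metric."""
    condition = "noise" if "noise" in table.columns else "spacing"
    out = (table.groupby(["method", condition, "metric"])["value"]
           .agg(["mean", "std"]).reset_index())
    return out
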