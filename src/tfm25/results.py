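"""Result containers shared by the inverse and direct reconstruction routes."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np

from .fields import TractionField

__all__ = ["ReconstructionResult", "DivergenceReport"]


@dataclass
class DivergenceReport:
    """Interior L2 norm of the stress divergence along the correction loop.

    ``norms[0]`` is the norm of the uncorrected input; ``norms[i]`` the norm
    after iteration ``i``.
    """

    norms: np.ndarray

    @property
    def ratio(self) -> float:
        """Final / initial divergence norm."""
        if self.norms[0] == 0:
            return 0.0
        return float(self.norms[-1] / self.norms[0])

    def first_below(self, fraction: float) -> int | None:
        """First iteration index at which the norm drops below
        ``fraction`` of its initial value, or None if it never does."""
        if self.norms[0] == 0:
            return 0
        hits = np.nonzero(self.norms <= fraction * self.norms[0])[0]
        return int(hits[0]) if hits.size else None


@dataclass
class ReconstructionResult:
    """A reconstructed traction field plus method diagnostics.

    ``lambda_used`` and ``gcv_curve`` are populated by the Fourier inverse
    route; ``divergence_report`` by the direct route when the divergence
    correction is enabled.
    """

    traction: TractionField
    lambda_used: float | None = None
    gcv_curve: np.ndarray | None = None  # (n, 2): lambda, G(lambda)
    divergence_report: DivergenceReport | None = None
    diagnostics: dict[str, Any] = field(default_factory=dict)
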