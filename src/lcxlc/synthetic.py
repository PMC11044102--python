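"""Synthetic analyte-set generation.

Stands in for an experimentally measured analyte parameter table (one
HILIC retention law, one RP-LC retention law and one van Deemter curve
per analyte per dimension) so every stage of the pipeline can be
exercised without instrument data.  Draws are log-uniform within ranges
typical for small phenolic compounds on amide (HILIC) and C18 (RP)
phases; a seed fixes all randomness.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .retention import Analyte, RetentionModel, VanDeemterCurve

__all__ = ["SyntheticSpec", "generate_synthetic_analytes"]


@dataclass(frozen=True)
class SyntheticSpec:
    """Parameter ranges (low, high) for log-uniform analyte draws.

    Defaults emulate phenolic standards spanning weakly to strongly
    retained behavior in both dimensions: ¹D HILIC adsorption law
    (k100 in [0.1, 2], n in [0.5, 3]) and ²D RP-LC LSS law
    (k0 in [5, 300], S in [8, 30]); van Deemter coefficients for sub-2 µm
    packings (a ~ 2 dp, modest b and c terms).
    """

    n_analytes: int = 10
    seed: int = 0
    k100_range: tuple[float, float] = (0.1, 2.0)
    n_range: tuple[float, float] = (0.5, 3.0)
    k0_range: tuple[float, float] = (5.0, 300.0)
    s_range: tuple[float, float] = (8.0, 30.0)
    vd_a_range: tuple[float, float] = (2.0, 4.0)  # µm
    vd_b_range: tuple[float, float] = (1.0, 5.0)  # µm·mm/s
    vd_c_range: tuple[float, float] = (0.1, 0.5)  # µm·s/mm

    def __post_init__(self) -> None:
        if self.n_analytes < 0:
            raise ValueError("n_analytes must be non-negative")
        for name in ("k100_range", "n_range", "k0_range", "s_range",
                     "vd_a_range", "vd_b_range", "vd_c_range"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"{name} must be positive with high >= low")


def _log_uniform(rng: np.random.Generator, lo: float, hi: float, n: int) -> np.ndarray:
    return np.exp(rng.uniform(np.log(lo), np.log(hi), size=n))


def generate_synthetic_analytes(spec: SyntheticSpec) -> list[Analyte]:
    """Draw a deterministic synthetic analyte set from ``spec``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_analytes
    k100 = _log_uniform(rng, *spec.k100_range, n)
    nn = _log_uniform(rng, *spec.n_range, n)
    k0 = _log_uniform(rng, *spec.k0_range, n)
    s = _log_uniform(rng, *spec.s_range, n)
    vd = {
        dim: tuple(
            _log_uniform(rng, *getattr(spec, f"vd_{c}_range"), n) for c in "abc"
        )
        for dim in ("d1", "d2")
    }
    analytes = []
    for i in range(n):
        analytes.append(
            Analyte(
                name=f"analyte_{i + 1:02d}",
                model_d1=RetentionModel.adsorption(float(k100[i]), float(nn[i])),
                model_d2=RetentionModel.lss(float(k0[i]), float(s[i])),
                vd_d1=VanDeemterCurve(*(float(v[i]) for v in vd["d1"])),
                vd_d2=VanDeemterCurve(*(float(v[i]) for v in vd["d2"])),
            )
        )
    return analytes
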