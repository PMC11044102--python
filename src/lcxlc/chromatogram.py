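"""Predicted two-dimensional chromatogram assembly.

A first-dimension peak (modeled as Gaussian — no ¹D overload is
simulated) is sliced into modulation fractions; each populated fraction
is simulated in the second dimension with that fraction's own
sample-solvent composition, and the resulting elution profiles, scaled
by the fraction mass shares, are assembled into a retention-plane
intensity matrix.  Fractions are rendered at the *midpoint* of their
sampling window on the ¹D axis.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm

from .craig import ElutionProfile

__all__ = [
    "FractionSlice",
    "Chromatogram2D",
    "slice_first_dimension",
    "build_2d_chromatogram",
    "simulate_chromatogram",
    "export_grid",
    "plot_contour",
]


@dataclass(frozen=True)
class FractionSlice:
    """One modulation fraction of a first-dimension peak."""

    index: int
    mass_share: float
    phi1_mean: float  # mean ¹D exit composition over the fraction window


@dataclass
class Chromatogram2D:
    """Retention-plane intensity grid with per-analyte contributions."""

    t1: np.ndarray  # min, fraction midpoints
    t2: np.ndarray  # min, simulator grid
    intensity: np.ndarray  # shape (len(t2), len(t1)), mass-flux units
    contributions: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def total_mass(self) -> float:
        """Integrated mass over the whole plane (²D time integral per column)."""
        if len(self.t2) < 2:
            return 0.0
        dt2 = float(self.t2[1] - self.t2[0])
        return float(self.intensity.sum() * dt2)


def slice_first_dimension(
    t_r1: float,
    sigma1: float,
    ts: float,
    window: float,
    phi_of_t: Callable[[float], float] | None = None,
    min_share: float = 1e-4,
) -> list[FractionSlice]:
    """Gaussian mass shares of a ¹D peak over consecutive sampling windows.

    Shares are exact Gaussian integrals over ``[i·ts, (i+1)·ts)``;
    fractions carrying less than ``min_share`` of the peak are dropped.
    ``phi_of_t`` (¹D exit composition vs time) supplies each fraction's
    mean transfer composition; when omitted the composition is NaN.
    """
    if sigma1 <= 0 or ts <= 0 or window <= 0:
        raise ValueError("sigma1, ts and window must be positive")
    n_frac = int(math.ceil(window / ts))
    edges = np.arange(n_frac + 1) * ts
    shares = norm.cdf(edges[1:], t_r1, sigma1) - norm.cdf(edges[:-1], t_r1, sigma1)
    out: list[FractionSlice] = []
    for i, share in enumerate(shares):
        if share < min_share:
            continue
        if phi_of_t is None:
            phi_mean = math.nan
        else:
            tt = np.linspace(edges[i], edges[i + 1], 17)
            phi_mean = float(np.mean([phi_of_t(float(t)) for t in tt]))
        out.append(FractionSlice(index=i, mass_share=float(share), phi1_mean=phi_mean))
    return out


def build_2d_chromatogram(
    ts: float,
    analyte_slices: dict[str, Sequence[FractionSlice]],
    profiles: dict[tuple[str, int], ElutionProfile],
) -> Chromatogram2D:
    """Assemble the retention-plane grid from per-fraction simulations.

    ``profiles`` maps ``(analyte name, fraction index)`` to the simulated
    ²D elution profile for that fraction; a missing pair for a populated
    fraction is an error naming it.  Each profile is scaled by the
    fraction's mass share, so the plane integrates to one mass unit per
    analyte.
    """
    if not analyte_slices:
        return Chromatogram2D(np.array([]), np.array([]), np.zeros((0, 0)))
    indices = sorted({s.index for slices in analyte_slices.values() for s in slices})
    dt_set = set()
    n_t2 = 0
    for (name, idx), prof in profiles.items():
        dt_set.add(round(prof.dt, 15))
        n_t2 = max(n_t2, len(prof.time))
    if len(dt_set) > 1:
        raise ValueError("all profiles must share one time step")
    for name, slices in analyte_slices.items():
        for s in slices:
            if (name, s.index) not in profiles:
                raise ValueError(f"missing simulation for analyte {name!r}, fraction {s.index}")
    dt = dt_set.pop()
    t2 = (np.arange(n_t2) + 1) * dt
    t1 = (np.array(indices) + 0.5) * ts  # midpoint rendering
    col_of = {idx: j for j, idx in enumerate(indices)}
    intensity = np.zeros((n_t2, len(indices)))
    contributions: dict[str, np.ndarray] = {}
    for name, slices in analyte_slices.items():
        contrib = np.zeros_like(intensity)
        for s in slices:
            prof = profiles[(name, s.index)]
            contrib[: len(prof.flux), col_of[s.index]] += s.mass_share * prof.flux
        contributions[name] = contrib
        intensity += contrib
    return Chromatogram2D(t1=t1, t2=t2, intensity=intensity, contributions=contributions)


def simulate_chromatogram(config, analytes, n_max: int = 20_000) -> Chromatogram2D:
    """Full predicted-chromatogram pipeline for one configuration.

    Slices every analyte's Gaussian ¹D peak into modulation fractions,
    runs one Craig simulation per populated fraction (each with that
    fraction's own mean transfer composition and sample solvent), and
    assembles the retention plane.  Analytes that do not elute in the
    ¹D are skipped with the evaluation-route warning.
    """
    from .craig import CraigColumn, make_injection_profile, simulate_elution
    from .metrics import column_state, modulation_geometry, sample_solvent_composition
    from .optimizer import _first_dimension
    from .retention import composition_at_inlet

    ts = config.modulation.sampling_time
    g1, g2 = config.gradient_d1, config.gradient_d2
    details = {a.name: (_first_dimension(config, a), a) for a in analytes}
    eluting = {n: da for n, da in details.items() if da[0].eluted}
    if not eluting:
        raise ValueError("no analyte elutes in the first dimension")
    window = max(d.t_r1 + 5.0 * d.sigma1 for d, _ in eluting.values())

    analyte_slices: dict[str, list[FractionSlice]] = {}
    profiles: dict[tuple[str, int], ElutionProfile] = {}
    for name, (d, analyte) in eluting.items():
        t0_1 = config.column_d1.void_volume / g1.flow

        def phi_exit(t: float) -> float:
            return float(composition_at_inlet(g1, max(t - t0_1, 0.0)))

        slices = slice_first_dimension(d.t_r1, d.sigma1, ts, window, phi_of_t=phi_exit)
        analyte_slices[name] = slices
        state2 = column_state(config.column_d2, analyte.vd_d2, g2.flow)
        n_plates = min(int(round(state2.n_plates)), n_max)
        geom = modulation_geometry(
            g1.flow, config.modulation.makeup_flow, ts, config.modulation.loop_volume
        )
        for s in slices:
            phi_ss = sample_solvent_composition(
                s.phi1_mean, g1.flow, config.modulation.makeup_flow,
                config.modulation.makeup_composition,
            )
            inj = make_injection_profile(
                loop_volume=config.modulation.loop_volume,
                fill_fraction=geom.fill_fraction,
                flow=g2.flow,
                sample_solvent=phi_ss,
                mobile_phase_init=g2.phi_init,
            )
            profiles[(name, s.index)] = simulate_elution(
                analyte.model_d2,
                CraigColumn(n_plates=n_plates, t0=state2.t0),
                g2,
                inj,
                analyte=f"{name}/f{s.index}",
            )
    return build_2d_chromatogram(ts, analyte_slices, profiles)


def export_grid(chrom: Chromatogram2D, long_path, dense_path=None) -> None:
    """Write the chromatogram as long-format and dense-matrix CSV.

    Long format: columns ``t1_min, t2_min, intensity`` (one row per
    cell); dense format: first column ``t2_min``, remaining columns one
    per ¹D coordinate.  An empty chromatogram yields header-only files.
    """
    import pandas as pd

    n2, n1 = chrom.intensity.shape
    rows = {
        "t1_min": np.repeat(chrom.t1, n2) if n1 else [],
        "t2_min": np.tile(chrom.t2, n1) if n1 else [],
        "intensity": chrom.intensity.T.ravel() if n1 else [],
    }
    pd.DataFrame(rows).to_csv(long_path, index=False)
    if dense_path is not None:
        dense = pd.DataFrame(
            chrom.intensity, columns=[f"{t:.6g}" for t in chrom.t1]
        )
        dense.insert(0, "t2_min", chrom.t2 if n1 else [])
        dense.to_csv(dense_path, index=False)


def plot_contour(chrom: Chromatogram2D, path=None, levels: int = 30):
    """Render the predicted 2D chromatogram as a contour plot (visual aid)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    if chrom.intensity.size:
        ax.contourf(chrom.t1, chrom.t2, chrom.intensity, levels=levels, cmap="viridis")
    ax.set_xlabel("$^1$D retention time (min)")
    ax.set_ylabel("$^2$D retention time (min)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
        return None
    return fig
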