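"""Brownian diffusion statistics from linked trajectories.

Displacements between consecutive detections (not necessarily consecutive
frames) are normalized by the square root of their actual lag time; the x-
and y-axis histograms are then fit globally — per-axis amplitudes, one shared
diffusion coefficient — with the Gaussian trial function
``G(u) = A * exp(-u**2 / (4*D))`` using Poisson-weighted least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = [
    "DisplacementSample",
    "DiffusionFit",
    "normalized_displacements",
    "fit_gaussian_D",
    "quantized_bin_edges",
]


@dataclass(frozen=True)
class DisplacementSample:
    """One normalized displacement u = Δ/√τ (µm·s^-1/2) on one axis."""

    u: float
    axis: str  # "x" or "y"
    tau_s: float

    def __post_init__(self) -> None:
        if self.tau_s <= 0:
            raise ValueError("tau_s must be positive")
        if self.axis not in ("x", "y"):
            raise ValueError("axis must be 'x' or 'y'")


@dataclass
class DiffusionFit:
    D: float  # µm²/s, shared across axes
    D_stderr: float
    amplitude: tuple[float, float]  # (A_x, A_y)
    n_samples: int
    bin_edges: np.ndarray
    bin_counts: tuple[np.ndarray, np.ndarray]  # (x counts, y counts)


def normalized_displacements(trajs, pixel_size_um: float | None = None,
                             frame_interval_s: float | None = None) -> list[DisplacementSample]:
    """Per-axis normalized displacements of consecutive trajectory samples.

    For each consecutive pair (t_i, p_i) -> (t_{i+1}, p_{i+1}):
    τ = (t_{i+1} - t_i) * frame_interval_s (multi-frame gaps keep their
    actual τ), u_x = Δcol * pixel_size_um / √τ, u_y = Δrow * pixel_size_um / √τ.
    Trajectories with fewer than 2 samples contribute nothing.
    """
    if pixel_size_um is None:
        pixel_size_um = getattr(trajs, "pixel_size_um", 1.0)
    if frame_interval_s is None:
        frame_interval_s = getattr(trajs, "frame_interval_s", 1.0)
    if pixel_size_um <= 0 or frame_interval_s <= 0:
        raise ValueError("calibration must be positive")
    samples: list[DisplacementSample] = []
    for traj in trajs.trajectories:
        for (t0, r0, c0), (t1, r1, c1) in zip(traj.samples, traj.samples[1:]):
            tau = (t1 - t0) * frame_interval_s
            sq = np.sqrt(tau)
            samples.append(DisplacementSample((c1 - c0) * pixel_size_um / sq, "x", tau))
            samples.append(DisplacementSample((r1 - r0) * pixel_size_um / sq, "y", tau))
    return samples


def _gaussian(u, A, D):
    return A * np.exp(-u ** 2 / (4.0 * D))


def quantized_bin_edges(samples: list[DisplacementSample], pixel_size_um: float,
                        frame_interval_s: float) -> np.ndarray:
    """Histogram edges aligned with the pixel-quantization comb.

    Tracked displacements are integer pixel multiples, so u values cluster at
    multiples of pixel_size/sqrt(frame_interval); bins one comb spacing wide,
    centered on the teeth, keep the weighted histogram fit well conditioned
    (narrower bins interleave empty, maximally-weighted bins between teeth).
    """
    h = pixel_size_um / np.sqrt(frame_interval_s)
    lim = max(max(abs(s.u) for s in samples), h)
    k = int(np.ceil(lim / h))
    return (np.arange(-k, k + 2) - 0.5) * h


def fit_gaussian_D(samples: list[DisplacementSample],
                   n_bins: "int | np.ndarray | None" = None,
                   min_samples: int = 50) -> DiffusionFit:
    """Global Gaussian fit of the x and y displacement histograms.

    Histograms share common bins: Freedman–Diaconis on the pooled samples by
    default; *n_bins* may be a count or explicit edges (for pixel-quantized
    displacements prefer :func:`quantized_bin_edges`).  The model has per-axis amplitudes A_x, A_y
    and one shared D; bins are weighted 1/max(count, 1) (Poisson statistics)
    in the nonlinear least-squares fit.

    Raises
    ------
    ValueError
        On too few samples, a missing axis, or degenerate (zero-spread) data.
    RuntimeError
        If the fit does not converge (diagnostics in the message).
    """
    ux = np.array([s.u for s in samples if s.axis == "x"])
    uy = np.array([s.u for s in samples if s.axis == "y"])
    if len(ux) + len(uy) < min_samples:
        raise ValueError(
            f"need >= {min_samples} samples; got {len(ux) + len(uy)}")
    if len(ux) == 0 or len(uy) == 0:
        raise ValueError("samples must span both axes for a global fit")
    pooled = np.concatenate([ux, uy])
    if np.ptp(pooled) == 0:
        raise ValueError("degenerate samples: zero spread")

    if n_bins is None:
        edges = np.histogram_bin_edges(pooled, bins="fd")
    else:
        edges = np.histogram_bin_edges(pooled, bins=n_bins)
    counts_x, _ = np.histogram(ux, bins=edges)
    counts_y, _ = np.histogram(uy, bins=edges)
    centers = 0.5 * (edges[:-1] + edges[1:])

    # stack both axes into one least-squares problem with a shared D
    u_all = np.concatenate([centers, centers])
    y_all = np.concatenate([counts_x, counts_y]).astype(float)
    is_x = np.concatenate([np.ones_like(centers), np.zeros_like(centers)])
    sigma = np.sqrt(np.maximum(y_all, 1.0))  # weight 1/max(count,1)

    def model(u, A_x, A_y, D):
        return (is_x * A_x + (1 - is_x) * A_y) * np.exp(-u ** 2 / (4.0 * D))

    D0 = max(float(np.var(pooled)) / 2.0, 1e-12)
    p0 = [max(counts_x.max(), 1.0), max(counts_y.max(), 1.0), D0]
    try:
        popt, pcov = curve_fit(model, u_all, y_all, p0=p0, sigma=sigma,
                               absolute_sigma=False, maxfev=20000,
                               bounds=([0, 0, 1e-15], [np.inf, np.inf, np.inf]))
    except RuntimeError as exc:
        raise RuntimeError(
            f"Gaussian fit failed to converge (n={len(pooled)}, "
            f"var={np.var(pooled):.3g}, bins={len(centers)}): {exc}") from exc
    D_stderr = float(np.sqrt(pcov[2, 2])) if np.isfinite(pcov[2, 2]) else float("nan")
    return DiffusionFit(D=float(popt[2]), D_stderr=D_stderr,
                        amplitude=(float(popt[0]), float(popt[1])),
                        n_samples=len(pooled), bin_edges=edges,
                        bin_counts=(counts_x, counts_y))


def plot_fit(fit: DiffusionFit, path=None):
    """Two-panel histogram + fitted Gaussian figure (x and y axes)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    centers = 0.5 * (fit.bin_edges[:-1] + fit.bin_edges[1:])
    fine = np.linspace(fit.bin_edges[0], fit.bin_edges[-1], 400)
    fig, axes = plt.subplots(1, 2, figsize=(9, 4), sharey=True)
    for ax, counts, A, name in zip(axes, fit.bin_counts, fit.amplitude, "xy"):
        ax.bar(centers, counts, width=np.diff(fit.bin_edges), alpha=0.5,
               label=f"$\\Delta {name}/\\sqrt{{\\tau}}$")
        ax.plot(fine, _gaussian(fine, A, fit.D), "r-", label="global fit")
        ax.set_xlabel(r"$u$ ($\mu m\, s^{-1/2}$)")
        ax.legend()
    axes[0].set_ylabel("counts")
    fig.suptitle(f"D = {fit.D:.4g} ± {fit.D_stderr:.2g} µm²/s")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return fig
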