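"""End-to-end pipeline: build -> solve -> attach -> analyze -> report.

Every run writes a manifest echoing all parameters; re-running from the
manifest reproduces byte-identical CSV/JSON outputs (figures are
rendered at fixed DPI with no timestamps).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import asdict
from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from . import io as vio
from .flow import solve_flow, wss_histogram, wss_vector_field
from .polarity import assign_regions, load_cell_points, map_cells_to_flow, pairs_to_frame
from .reconstruct import (
    BinaryMask,
    build_network,
    caliber_histogram,
    diagnose_overlaps,
)
from .stats import (
    directionality_table,
    kuiper_one_sample,
    polar_histogram,
    rayleigh_test,
    scalar_product_slopes,
    sensor_analysis,
)

logger = logging.getLogger("vaspol")

__all__ = ["run_pipeline", "analyze_pairs"]

COPLANARITY_WARNING = (
    "degree-4 branch points detected (nodes {nodes}): vessels crossing at "
    "different depths appear connected in a z-projection; hemodynamics near "
    "these junctions are unreliable"
)


def _fig_path(outdir: Path, name: str) -> Path:
    return outdir / f"{name}.png"


def _save_json(obj, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def analyze_pairs(df: pd.DataFrame, cfg: dict, outdir: Path) -> dict:
    """Run the four statistical analyses on a cells-with-flow table.

    Writes CSV/JSON tables plus the polar-histogram, sensor-curve and
    slope-scatter figures; returns a machine-readable results dict.
    """
    a = cfg["analysis"]
    tol = float(a["tolerance_deg"])
    matched = df[df["matched"] & np.isfinite(df["theta_deg"])]
    theta = matched["theta_deg"].to_numpy()
    tau = matched["t_mag_pa"].to_numpy()
    s = matched["s"].to_numpy()
    regions = matched["region"].to_numpy()

    results: dict = {"n_cells": int(len(df)), "n_matched": int(len(matched))}

    # 1. directionality table
    table = directionality_table(theta, groups=regions, tolerance_deg=tol)
    rows = [
        {"group": g, **vals} for g, vals in table.groups.items()
    ]
    pd.DataFrame(rows).to_csv(outdir / "directionality.csv", index=False)
    results["directionality"] = table.groups

    # 2. polar histogram + uniformity tests
    nb = int(a.get("polar_bins", 24))
    hists = {"all": polar_histogram(theta, n_bins=nb)}
    for g in sorted(set(regions.tolist())):
        hists[str(g)] = polar_histogram(theta[regions == g], n_bins=nb, group=str(g))
    hist_rows = []
    for g, h in hists.items():
        for lo, hi, c in zip(h.bin_edges_deg[:-1], h.bin_edges_deg[1:], h.counts):
            hist_rows.append({"group": g, "bin_lo_deg": lo, "bin_hi_deg": hi, "count": int(c)})
    pd.DataFrame(hist_rows).to_csv(outdir / "polar_histogram.csv", index=False)
    folded = polar_histogram(theta, n_bins=max(nb // 2, 1), folded=True)
    pd.DataFrame(
        {
            "bin_lo_deg": folded.bin_edges_deg[:-1],
            "bin_hi_deg": folded.bin_edges_deg[1:],
            "count": folded.counts.astype(int),
        }
    ).to_csv(outdir / "polar_histogram_folded.csv", index=False)

    kuiper = {}
    if len(theta):
        k = kuiper_one_sample(theta, seed=int(a["seed"]))
        z, pz = rayleigh_test(theta)
        kuiper["all"] = {
            "kuiper_V": k.statistic,
            "kuiper_p": k.pvalue,
            "n": k.n,
            "method": k.method,
            "rayleigh_z": z,
            "rayleigh_p": pz,
        }
    for g in sorted(set(regions.tolist())):
        sub = theta[regions == g]
        if len(sub):
            k = kuiper_one_sample(sub, seed=int(a["seed"]))
            kuiper[str(g)] = {
                "kuiper_V": k.statistic,
                "kuiper_p": k.pvalue,
                "n": k.n,
                "method": k.method,
            }
    _save_json(kuiper, outdir / "kuiper.json")
    results["uniformity_tests"] = kuiper

    fig, ax = plt.subplots(subplot_kw={"projection": "polar"}, figsize=(5, 5))
    h = hists["all"]
    centers = np.deg2rad((h.bin_edges_deg[:-1] + h.bin_edges_deg[1:]) / 2)
    width = np.deg2rad(np.diff(h.bin_edges_deg))
    ax.bar(centers, h.counts, width=width, color="steelblue", edgecolor="k", alpha=0.8)
    ax.set_title("polarity angle vs flow (0 deg = with flow)")
    fig.savefig(_fig_path(outdir, "polar_histogram"), dpi=150)
    plt.close(fig)

    # 3. WSS sensor analysis
    sensor = None
    nbins = int(a["n_bins"])
    if len(matched) >= nbins:
        sensor = sensor_analysis(
            tau,
            theta,
            n_bins=nbins,
            tolerance_deg=tol,
            threshold_frac=float(a["threshold_frac"]),
        )
        pd.DataFrame(
            {
                "bin_median_tau_pa": sensor.bin_median_tau,
                "n": sensor.n_per_bin,
                "fraction_against": sensor.fraction_against,
            }
        ).to_csv(outdir / "sensor_curve.csv", index=False)
        results["sensor"] = {
            "threshold_tau_pa": sensor.threshold_tau,
            "threshold_frac": sensor.threshold_frac,
            "note": sensor.threshold_note,
        }
        fig, ax = plt.subplots(figsize=(5, 4))
        ax.plot(sensor.bin_median_tau, 100 * sensor.fraction_against, "o-")
        ax.axhline(100 * sensor.threshold_frac, ls="--", c="gray")
        if sensor.threshold_tau is not None:
            ax.axvline(sensor.threshold_tau, ls=":", c="firebrick")
        ax.set_xlabel("WSS magnitude (Pa)")
        ax.set_ylabel("% cells polarized against flow")
        fig.tight_layout()
        fig.savefig(_fig_path(outdir, "sensor_curve"), dpi=150)
        plt.close(fig)
    else:
        results["sensor"] = {"threshold_tau_pa": None, "note": "too few matched cells"}

    # 4. scalar-product slopes
    fits = scalar_product_slopes(s, tau)
    n_zero = int(np.sum(s == 0.0))
    slope_json = {f.subgroup: asdict(f) for f in fits}
    slope_json["n_zero"] = n_zero
    _save_json(slope_json, outdir / "slope_fits.json")
    results["slopes"] = slope_json

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.scatter(tau, s, s=8, alpha=0.5)
    for f in fits:
        if f.slope is not None:
            xs = np.linspace(0, tau.max() if len(tau) else 1, 50)
            ax.plot(xs, f.intercept + f.slope * xs,
                    label=f"{f.subgroup}: slope {f.slope:.3g}, r {f.pearson_r:.2f}")
    ax.axhline(0, c="k", lw=0.5)
    ax.set_xlabel("||t|| (Pa)")
    ax.set_ylabel("p . t (Pa um)")
    if any(f.slope is not None for f in fits):
        ax.legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(_fig_path(outdir, "slope_scatter"), dpi=150)
    plt.close(fig)

    return results


def run_pipeline(
    mask: BinaryMask,
    cells_table: pd.DataFrame | str,
    cfg: dict,
    outdir: str | Path,
    bcs=None,
    regions=None,
) -> dict:
    """Execute build -> solve -> attach -> analyze and write the bundle.

    ``bcs`` may be given directly (list of BoundaryCondition) or come
    from the config's ``boundary_conditions`` table.  Returns the
    results dict (also written as results.json next to the figures).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    stage = "build-network"
    try:
        net = build_network(mask, float(cfg["min_spur_factor"]))
        flagged = diagnose_overlaps(net)
        if flagged:
            msg = COPLANARITY_WARNING.format(nodes=flagged)
            warnings.warn(msg, stacklevel=2)
            logger.warning(msg)
        vio.write_network(net, outdir / "network")
        cal = caliber_histogram(net)
        pd.DataFrame(
            {
                "bin_lo_um": cal.bin_edges[:-1],
                "bin_hi_um": cal.bin_edges[1:],
                "weight_um": cal.counts,
            }
        ).to_csv(outdir / "caliber_histogram.csv", index=False)

        stage = "solve-flow"
        if bcs is None:
            bcs = vio.bcs_from_config(cfg)
        if not bcs:
            raise ValueError("no boundary conditions supplied")
        rheology = vio.rheology_from_config(cfg)
        sv = cfg["solver"]
        sol = solve_flow(
            net,
            bcs,
            rheology,
            tol=float(sv["tol"]),
            max_iter=int(sv["max_iter"]),
            relaxation=float(sv["relaxation"]),
        )
        vio.write_solution(net, sol, outdir / "flow")
        spacing = float(cfg["analysis"]["sample_spacing_um"])
        samples = wss_vector_field(net, sol, spacing)
        vio.write_wss_samples(samples, outdir / "wss_samples.csv")
        w_edges, w_counts, w_summary = wss_histogram(net, sol)
        pd.DataFrame(
            {"bin_lo_pa": w_edges[:-1], "bin_hi_pa": w_edges[1:], "weight_um": w_counts}
        ).to_csv(outdir / "wss_histogram.csv", index=False)

        stage = "attach-flow"
        cells = load_cell_points(cells_table, float(cfg["pixel_size_um"]))
        if regions:
            assign_regions(cells, regions)
        pairs = map_cells_to_flow(
            cells,
            net,
            sol,
            max_distance=float(cfg["analysis"]["max_distance_um"]),
            samples=samples,
        )
        df = pairs_to_frame(pairs)
        df.to_csv(outdir / "cells_with_flow.csv", index=False)

        stage = "analyze"
        results = analyze_pairs(df, cfg, outdir)
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    results["wss_summary"] = w_summary
    results["degree4_nodes"] = flagged
    results["unperfused_edges"] = sol.unperfused_edges
    results["solver_iterations"] = sol.iterations

    # remaining figures: overlay + caliber/WSS histograms
    _render_overlay(mask, cells, samples, outdir)
    _render_histogram(
        cal.bin_edges, cal.counts, "vessel diameter (um)", "length (um)",
        _fig_path(outdir, "caliber_histogram"),
    )
    _render_histogram(
        w_edges, w_counts, "WSS magnitude (Pa)", "length (um)",
        _fig_path(outdir, "wss_histogram"),
    )

    _save_json(results, outdir / "results.json")
    manifest = {
        "config": cfg,
        "outputs": sorted(p.name for p in outdir.iterdir() if p.name != "manifest.json"),
    }
    _save_json(manifest, outdir / "manifest.json")
    return results


def _render_overlay(mask: BinaryMask, cells, samples, outdir: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 7))
    extent = (
        0,
        mask.pixels.shape[1] * mask.pixel_size,
        mask.pixels.shape[0] * mask.pixel_size,
        0,
    )
    ax.imshow(mask.pixels, cmap="gray_r", alpha=0.4, extent=extent)
    taus = np.array([s.tau for s in samples])
    scale = np.percentile(taus[taus > 0], 90) if (taus > 0).any() else 1.0
    step = max(1, len(samples) // 600)
    for s in samples[::step]:
        if s.tau > 0:
            ax.annotate(
                "",
                xy=(s.x + 4 * s.tx / scale, s.y + 4 * s.ty / scale),
                xytext=(s.x, s.y),
                arrowprops={"arrowstyle": "->", "color": "firebrick", "lw": 0.6},
            )
    if cells:
        nx_ = np.array([c.nucleus[0] for c in cells])
        ny_ = np.array([c.nucleus[1] for c in cells])
        px = np.array([c.polarity[0] for c in cells])
        py = np.array([c.polarity[1] for c in cells])
        ax.quiver(
            nx_, ny_, px, py, angles="xy", scale_units="xy", scale=1.0,
            color="royalblue", width=0.002,
        )
    ax.set_xlabel("x (um)")
    ax.set_ylabel("y (um)")
    ax.set_title("mask (gray), polarity vectors (blue), WSS vectors (red)")
    fig.tight_layout()
    fig.savefig(_fig_path(outdir, "overlay"), dpi=150)
    plt.close(fig)


def _render_histogram(edges, counts, xlabel, ylabel, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.bar(edges[:-1], counts, width=np.diff(edges), align="edge",
           color="slategray", edgecolor="k")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
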