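"""Serialization and figure rendering for study outputs.

A rendered study directory always contains the result CSVs, the config
snapshot (with master seed) needed to regenerate it exactly, a
machine-readable summary and a log file; plots are emitted per
orientation present in the result.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
import yaml

from .msd import DisplacementProfile
from .study import StudyResult
from .synth import RFEnsemble

__all__ = [
    "render_outputs",
    "save_rf_ensemble",
    "load_rf_ensemble",
    "save_displacement_ensemble",
    "load_displacement_ensemble",
    "write_parametric_map",
]

_CSV_FLOAT = "%.12g"


def save_rf_ensemble(ens: RFEnsemble, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        d = f.create_dataset("rf", data=ens.rf)
        d.attrs.update(
            {
                "fs": ens.fs,
                "track_freq": ens.track_freq,
                "snr_db": ens.snr_db,
                "seed": ens.seed,
                "c_sound": ens.c_sound,
                "depth0": ens.depth0,
                "roi_lo": ens.roi[0],
                "roi_hi": ens.roi[1],
            }
        )
        f.create_dataset("sample_times", data=ens.sample_times)


def load_rf_ensemble(path: str | Path) -> RFEnsemble:
    with h5py.File(path, "r") as f:
        d = f["rf"]
        a = d.attrs
        return RFEnsemble(
            rf=d[()],
            fs=float(a["fs"]),
            track_freq=float(a["track_freq"]),
            snr_db=float(a["snr_db"]),
            seed=int(a["seed"]),
            c_sound=float(a["c_sound"]),
            depth0=float(a["depth0"]),
            sample_times=f["sample_times"][()],
            roi=(float(a["roi_lo"]), float(a["roi_hi"])),
        )


def save_displacement_ensemble(profiles: list[DisplacementProfile], path: str | Path) -> None:
    """Stacked two-column-per-profile CSV: shared t_s column, one z_m column per depth."""
    data = {"t_s": profiles[0].times}
    for p in profiles:
        data[f"z_m_depth_{p.location[0]:.6f}"] = p.z
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.17g")


def load_displacement_ensemble(path: str | Path) -> list[DisplacementProfile]:
    table = pd.read_csv(path)
    t = table["t_s"].to_numpy()
    out = []
    for i, col in enumerate(c for c in table.columns if c.startswith("z_m_depth_")):
        depth = float(col.removeprefix("z_m_depth_"))
        out.append(DisplacementProfile(times=t, z=table[col].to_numpy(), location=(depth, i)))
    return out


def write_parametric_map(
    re_map: np.ndarray,
    depths_mm: np.ndarray,
    lateral_mm: np.ndarray,
    out_base: str | Path,
) -> None:
    """Write a depth x lateral RE image as CSV matrix and rendered PNG."""
    out_base = Path(out_base)
    pd.DataFrame(re_map, index=depths_mm, columns=lateral_mm).to_csv(
        out_base.with_suffix(".csv"), float_format=_CSV_FLOAT
    )
    fig, ax = plt.subplots(figsize=(5, 4))
    im = ax.imshow(
        re_map,
        aspect="auto",
        extent=(lateral_mm[0], lateral_mm[-1], depths_mm[-1], depths_mm[0]),
        cmap="viridis",
    )
    fig.colorbar(im, ax=ax, label="RE (1/m)")
    ax.set_xlabel("lateral (mm)")
    ax.set_ylabel("depth (mm)")
    fig.tight_layout()
    fig.savefig(out_base.with_suffix(".png"), dpi=120)
    plt.close(fig)


def _plot_vs_angle(table: pd.DataFrame, value: str, ylabel: str, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(6, 4))
    for label, grp in table.groupby("label"):
        agg = grp.groupby("incidence_deg")[value].agg(["mean", "std"])
        ax.errorbar(agg.index, agg["mean"], yerr=agg["std"], marker="o", label=label)
    ax.set_xlabel("ARF-AoS incidence angle (deg)")
    ax.set_ylabel(ylabel)
    ax.invert_xaxis()
    ax.legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def render_outputs(result: StudyResult, out_dir: str | Path) -> list[Path]:
    """Write all tables, config snapshot, summary, log and plots; returns paths."""
    out = Path(out_dir)
    try:
        out.mkdir(parents=True, exist_ok=True)
    except OSError as e:
        raise OSError(f"cannot create output directory {out}: {e}") from e
    written: list[Path] = []

    tables = {
        "re_by_angle.csv": result.re_table,
        "dre_by_angle.csv": result.dre_table,
        "spearman_by_angle.csv": result.spearman_table,
        "slopes.csv": result.slopes_table,
        "wilcoxon_pairs.csv": result.wilcoxon_table,
    }
    for name, table in tables.items():
        path = out / name
        table.to_csv(path, index=False, float_format=_CSV_FLOAT)
        written.append(path)

    cfg_path = out / "config.yaml"
    cfg_path.write_text(yaml.safe_dump(result.config, sort_keys=False))
    written.append(cfg_path)

    summary = {
        "master_seed": result.config.get("master_seed"),
        "n_materials": int(result.re_table["label"].nunique()),
        "orientations": sorted(result.re_table["orientation"].unique().tolist()),
        "n_unconverged_fits": int(result.n_unconverged),
        "n_flagged_ncc": int(result.n_flagged),
        "spearman_by_angle": {
            orientation: {
                f"{row.incidence_deg:g}": round(float(row.rho), 6)
                for row in grp.itertuples()
            }
            for orientation, grp in (
                result.spearman_table.groupby("orientation")
                if not result.spearman_table.empty
                else []
            )
        },
        "n_significant_wilcoxon_pairs": int(result.wilcoxon_table["significant"].sum())
        if not result.wilcoxon_table.empty
        else 0,
    }
    summary_path = out / "summary.json"
    summary_path.write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n")
    written.append(summary_path)

    log_path = out / "study.log"
    log_path.write_text(
        "seed={}\nunconverged_fits={}\nflagged_ncc={}\n".format(
            result.config.get("master_seed"), result.n_unconverged, result.n_flagged
        )
    )
    written.append(log_path)

    for orientation, grp in result.re_table.groupby("orientation"):
        p = out / f"re_vs_angle_{orientation}.png"
        _plot_vs_angle(grp, "re_mean", "RE (1/m)", p)
        written.append(p)
    for orientation, grp in result.dre_table.groupby("orientation"):
        p = out / f"dre_vs_angle_{orientation}.png"
        _plot_vs_angle(grp, "dre_pct", r"$\Delta$RE (%)", p)
        written.append(p)

    if not result.slopes_table.empty and "longitudinal" in set(
        result.slopes_table["orientation"]
    ):
        sl = result.slopes_table[result.slopes_table.orientation == "longitudinal"]
        fig, ax = plt.subplots(figsize=(6, 4))
        agg = sl.groupby(["label", "muL_over_EL"])["slope_pct_per_deg"].agg(
            ["mean", "std"]
        )
        agg = agg.reset_index().sort_values("muL_over_EL")
        ax.errorbar(agg["muL_over_EL"], agg["mean"], yerr=agg["std"], fmt="o")
        ax.set_xlabel(r"$\mu_L / E_L$")
        ax.set_ylabel(r"slope of $\Delta$RE vs deviation angle (%/deg)")
        fig.tight_layout()
        p = out / "slope_vs_ratio.png"
        fig.savefig(p, dpi=120)
        plt.close(fig)
        written.append(p)
    return written
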