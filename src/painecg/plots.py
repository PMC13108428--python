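"""Optional figure output for pipeline runs (PNG, matplotlib Agg backend)."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def importance_bars(imp: pd.DataFrame, path: Path) -> None:
    fig, ax = plt.subplots(figsize=(7, 4))
    order = imp.sort_values("importance_mean_permutation")
    ax.barh(order["feature"], order["importance_mean_permutation"], color="#4477aa")
    ax.set_xlabel("permutation importance (accuracy drop)")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pdp_ice_overlay(pdp_payload: dict, path: Path) -> None:
    n = len(pdp_payload)
    fig, axes = plt.subplots(1, max(n, 1), figsize=(4 * max(n, 1), 3.2), squeeze=False)
    for ax, (feat, data) in zip(axes[0], pdp_payload.items()):
        grid = np.asarray(data["grid"])
        for curve in data["ice"]:
            ax.plot(grid, curve, color="#88aadd", lw=0.5, alpha=0.5)
        ax.plot(grid, data["pd"], color="#223366", lw=2.0, ls="--", label="PD")
        ax.set_xlabel(f"{feat} (standardized)")
        ax.set_ylabel("P(pain)")
        ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def bland_altman_plot(metrics: dict, path: Path) -> None:
    ba = metrics.get("bland_altman")
    if not ba:
        return
    fig, ax = plt.subplots(figsize=(5, 4))
    ax.axhline(ba["bias"], color="black", label=f"bias {ba['bias']:.2f}")
    for key in ("loa_low", "loa_high"):
        ax.axhline(ba[key], color="red", ls="--")
    ax.set_xlabel("mean of predicted and actual CoVAS")
    ax.set_ylabel("predicted - actual")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def run_plots(out: Path, metrics: dict, imp: pd.DataFrame, pdp_payload: dict) -> None:
    importance_bars(imp, out / "importances.png")
    pdp_ice_overlay(pdp_payload, out / "pdp_ice.png")
    bland_altman_plot(metrics, out / "bland_altman.png")
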