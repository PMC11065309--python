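"""Report rendering, run manifests, and plots.

Display rounding: GBP to 2 dp, QALYs and probabilities to 4 dp; machine
outputs (JSON/CSV) keep full precision.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .engine import ArmResult, IncrementalResult
from .psa import PSAResult


def round_gbp(x: float) -> float:
    return round(float(x), 2)


def round_qaly(x: float) -> float:
    return round(float(x), 4)


def base_case_frame(result: Mapping) -> pd.DataFrame:
    """Cost-effectiveness table: one row per quantity, per-arm columns and an
    incremental column."""
    arms: Mapping[str, ArmResult] = result["arms"]
    i, c = arms["intervention"], arms["control"]
    life: IncrementalResult = result["lifetime"]
    short: IncrementalResult = result["short_term"]
    rows = [
        ("hospital_cost_gbp", i.hospital_cost, c.hospital_cost, short.delta_cost),
        ("lifetime_cost_gbp", i.lifetime_cost, c.lifetime_cost, i.lifetime_cost - c.lifetime_cost),
        ("total_cost_gbp", i.total_cost, c.total_cost, life.delta_cost),
        ("events_per_patient", i.expected_events, c.expected_events,
         i.expected_events - c.expected_events),
        ("qale", i.qale, c.qale, life.delta_effect),
    ]
    return pd.DataFrame(rows, columns=["quantity", "intervention", "control", "incremental"])


def base_case_report(result: Mapping) -> dict:
    """JSON-ready base-case report (full precision)."""
    life: IncrementalResult = result["lifetime"]
    short: IncrementalResult = result["short_term"]
    return {
        "arms": {a: asdict(r) | {"total_cost": r.total_cost}
                 for a, r in result["arms"].items()},
        "lifetime": asdict(life) | {"nmb": life.nmb, "nhb": life.nhb},
        "short_term": asdict(short) | {"nmb": short.nmb},
    }


def render_base_case_text(result: Mapping) -> str:
    """Human-readable summary mirroring the per-arm / incremental layout."""
    frame = base_case_frame(result)
    life: IncrementalResult = result["lifetime"]
    lines = [f"{'quantity':<22}{'intervention':>14}{'control':>14}{'incremental':>14}"]
    for _, row in frame.iterrows():
        if row["quantity"].endswith("_gbp"):
            fmt = lambda v: f"{round_gbp(v):,.2f}"
        else:
            fmt = lambda v: f"{round_qaly(v):.4f}"
        lines.append(f"{row['quantity']:<22}{fmt(row['intervention']):>14}"
                     f"{fmt(row['control']):>14}{fmt(row['incremental']):>14}")
    verdict = life.dominance if life.dominance != "icer" else f"ICER {round_gbp(life.icer):,.2f}/QALY"
    lines.append(f"lifetime verdict: {verdict} "
                 f"(NMB at {life.wtp:,.0f}: {round_gbp(life.nmb):,.2f})")
    return "\n".join(lines)


def psa_summary(result: PSAResult) -> dict:
    if result.n_draws == 0:
        return {"n_draws": 0, "note": "zero draws"}
    ceac_vals = result.ceac()
    return {
        "n_draws": result.n_draws,
        "n_failed": result.n_failed,
        "means": result.means(),
        "central_range": {
            "delta_cost": result.central_range("delta_cost"),
            "delta_qaly": result.central_range("delta_qaly"),
        },
        "quadrant_proportions": result.quadrant_proportions(),
        "ceac": {str(int(w)): float(p) for w, p in zip(result.config.wtp_grid, ceac_vals)},
    }


def ceac_frame(result: PSAResult) -> pd.DataFrame:
    return pd.DataFrame({"wtp": list(result.config.wtp_grid),
                         "p_cost_effective": result.ceac()})


def psa_draws_frame(result: PSAResult) -> pd.DataFrame:
    return pd.DataFrame({
        "delta_cost": result.delta_cost,
        "delta_qaly": result.delta_qaly,
        "delta_hospital_cost": result.delta_hospital_cost,
        "delta_events_avoided": result.delta_events,
    })


def plot_ce_plane(result: PSAResult, path: str | Path, wtp: float = 20_000.0) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 5))
    ax.scatter(result.delta_qaly, result.delta_cost, s=4, alpha=0.25, edgecolors="none")
    ax.axhline(0, color="k", lw=0.8)
    ax.axvline(0, color="k", lw=0.8)
    q = np.linspace(*ax.get_xlim(), 10)
    ax.plot(q, wtp * q, "r--", lw=0.8, label=f"wtp = {wtp:,.0f}/QALY")
    ax.set_xlabel("Incremental QALYs")
    ax.set_ylabel("Incremental cost (GBP)")
    ax.set_title("Cost-effectiveness plane (lifetime horizon)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_ceac(result: PSAResult, path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frame = ceac_frame(result)
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.plot(frame["wtp"], frame["p_cost_effective"])
    ax.set_ylim(0, 1)
    ax.set_xlabel("Willingness to pay (GBP per QALY)")
    ax.set_ylabel("P(cost-effective)")
    ax.set_title("Cost-effectiveness acceptability curve")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


# ---------------------------------------------------------------------------
# Manifests

def _file_sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def build_manifest(command: str, config_path: str | Path | None, seed: int,
                   outputs: list[Path], stage_seeds: Mapping[str, int] | None = None) -> dict:
    from . import __version__
    return {
        "command": command,
        "config": str(config_path) if config_path else "<bundled base case>",
        "config_sha256": _file_sha256(Path(config_path)) if config_path else None,
        "seed": seed,
        "stage_seeds": dict(stage_seeds or {}),
        "package_version": __version__,
        "timestamp_utc": datetime.now(timezone.utc).isoformat(),
        "outputs": [str(p) for p in outputs],
    }


def write_json(obj, path: str | Path) -> None:
    def default(o):
        if isinstance(o, (np.floating, np.integer)):
            return o.item()
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, float) and math.isnan(o):
            return None
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default) + "\n")
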