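"""Simulation-trace figures: policy probabilities, rewards, prediction error,
and the evolving risky-arm reward estimates."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .agent_loop import SimulationTrace


def plot_trace(trace: SimulationTrace, out_dir) -> list:
    """Write the standard simulation panels as PNG files; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    frame = trace.to_frame()
    paths = []

    fig, axes = plt.subplots(5, 1, figsize=(9, 12), sharex=True)
    axes[0].plot(frame["trial"], frame["p_cue"], color="tab:green", lw=1)
    axes[0].set_ylabel("P(Cue)")
    axes[1].plot(frame["trial"], frame["p_risky"], color="tab:blue", lw=1)
    axes[1].set_ylabel("P(Risky)")
    axes[2].bar(frame["trial"], frame["reward"], color="tab:gray")
    axes[2].set_ylabel("reward")
    axes[3].plot(frame["trial"], frame["prediction_error"], color="tab:red", lw=1)
    axes[3].set_ylabel("|prediction error|")
    axes[4].plot(frame["trial"], frame["est_risky_ctx1"], label="Context 1")
    axes[4].plot(frame["trial"], frame["est_risky_ctx2"], label="Context 2")
    axes[4].set_ylabel("E[risky reward]")
    axes[4].set_xlabel("trial")
    axes[4].legend()
    fig.tight_layout()
    path = out_dir / "simulation_trace.png"
    fig.savefig(path, dpi=120)
    plt.close(fig)
    paths.append(path)
    return paths
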