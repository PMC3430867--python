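"""Vincentized defective-quantile plots of data and model fits."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_vincentized(report, path) -> None:
    """Defective quantile-probability plot per session from an AnalysisReport.

    Error-response quantiles are drawn at negative cumulative probability
    (mirrored to the left), correct responses to the right, so each cue's
    curve traces the full defective RT distribution; model-implied
    quantiles, when present, are overlaid as open markers.
    """
    vinc = report.vincentized
    sessions = sorted({k.split("/")[0] for k in vinc})
    fig, axes = plt.subplots(1, len(sessions), figsize=(5 * len(sessions), 4),
                             sharey=True, squeeze=False)
    for ax, session in zip(axes[0], sessions):
        for cue, color in (("speed", "tab:red"), ("accuracy", "tab:blue")):
            entry = vinc[f"{session}/{cue}"]
            obs = entry["observed"]
            probs = np.asarray(obs["probs"])
            pc = obs["p_correct"]
            xc = probs * pc
            ax.plot(xc, obs["correct_quantiles"], "o-", color=color,
                    label=f"{cue} correct")
            if obs["error_quantiles"] is not None:
                ax.plot(-probs * (1 - pc), obs["error_quantiles"], "s--",
                        color=color, alpha=0.6, label=f"{cue} error")
            pred = entry.get("ddm_predicted")
            if pred:
                ax.plot(probs * pred["p_correct"], pred["correct"], "^",
                        mfc="none", color=color)
        ax.axvline(0, color="grey", lw=0.5)
        ax.set_title(session)
        ax.set_xlabel("defective cumulative probability\n(errors left, correct right)")
    axes[0][0].set_ylabel("RT quantile (s)")
    axes[0][0].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
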