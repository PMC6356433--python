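"""Rendering of the survival and GLM outputs (KM step plot, coefficient bars).

Figures are written deterministically: a fixed SVG hash salt and suppressed
date metadata make repeated renders byte-identical for identical inputs.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .survival import GlmResult, LogRankResult, SurvivalCurve

plt.rcParams["svg.hashsalt"] = "bindsig"


def _step_xy(curve: SurvivalCurve, t_max: float) -> tuple[list[float], list[float]]:
    xs, ys = [0.0], [1.0]
    s_prev = 1.0
    for t, s in zip(curve.times, curve.survival):
        xs += [float(t), float(t)]
        ys += [s_prev, float(s)]
        s_prev = float(s)
    xs.append(t_max)
    ys.append(s_prev)
    return xs, ys


def _stars(p: float) -> str:
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def plot_km(
    curves: dict[str, SurvivalCurve],
    logrank: LogRankResult | None,
    path: str | Path,
) -> None:
    """Kaplan-Meier step plot with censoring ticks and a log-rank p annotation."""
    fig, ax = plt.subplots(figsize=(6, 4.5))
    t_max = max(
        [c.times[-1] if len(c.times) else 0.0 for c in curves.values()]
        + [c.censor_times[-1] if len(c.censor_times) else 0.0 for c in curves.values()]
        + [1.0]
    )
    colors = {"high": "#c0392b", "low": "#2980b9"}
    for i, (label, curve) in enumerate(sorted(curves.items())):
        xs, ys = _step_xy(curve, t_max)
        color = colors.get(label, f"C{i}")
        ax.plot(xs, ys, drawstyle="default", color=color, label=label)
        if len(curve.censor_times):
            # S just before each censoring time, for tick placement
            s_at = []
            for ct in curve.censor_times:
                mask = curve.times <= ct
                s_at.append(curve.survival[mask][-1] if mask.any() else 1.0)
            ax.plot(curve.censor_times, s_at, "|", color=color, markersize=6)
    if logrank is not None:
        ax.text(0.55, 0.9, f"log-rank p = {logrank.p_value:.3g}",
                transform=ax.transAxes)
    ax.set_xlabel("time (days)")
    ax.set_ylabel("overall survival")
    ax.set_ylim(0, 1.02)
    ax.legend(title="signature score")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def plot_glm_coefficients(glms: Sequence[GlmResult], path: str | Path) -> None:
    """Bar plot of per-feature GLM estimates with significance stars."""
    fig, ax = plt.subplots(figsize=(6, 4))
    names = [g.feature for g in glms]
    estimates = [g.estimate for g in glms]
    errors = [g.std_error if g.std_error == g.std_error else 0.0 for g in glms]
    pos = range(len(glms))
    ax.bar(pos, estimates, yerr=errors, capsize=3, color="#7f8c8d")
    for i, g in enumerate(glms):
        if g.p_value == g.p_value:
            ax.annotate(_stars(g.p_value), (i, g.estimate),
                        ha="center", va="bottom")
    ax.axhline(0, color="black", linewidth=0.8)
    ax.set_xticks(list(pos))
    ax.set_xticklabels(names, rotation=30, ha="right")
    ax.set_ylabel("estimate")
    fig.tight_layout()
    fig.savefig(path, metadata={"Date": None})
    plt.close(fig)


def write_survival_tsv(curves: dict[str, SurvivalCurve], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("group\ttime\tat_risk\tdeaths\tsurvival\n")
        for label, c in sorted(curves.items()):
            for t, n, d, s in zip(c.times, c.at_risk, c.deaths, c.survival):
                fh.write(f"{label}\t{t:g}\t{n:g}\t{d:g}\t{s:.10g}\n")


def write_glm_tsv(glms: Sequence[GlmResult], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("feature\tfamily\testimate\tstd_error\tstatistic\tp_value\tn\tconverged\n")
        for g in glms:
            fh.write(
                f"{g.feature}\t{g.family}\t{g.estimate:.10g}\t{g.std_error:.10g}\t"
                f"{g.statistic:.10g}\t{g.p_value:.10g}\t{g.n}\t{int(g.converged)}\n"
            )
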