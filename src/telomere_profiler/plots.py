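"""Optional diagnostic plots (simple equivalents of the standard panels).

All results are available as TSV regardless; plotting is a convenience
and off by default in library use.
"""

from __future__ import annotations

import os
from typing import TYPE_CHECKING

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

if TYPE_CHECKING:
    from telomere_profiler.pipeline import RunResult


def plot_content_bar(run: "RunResult", path: str) -> None:
    samples, values = [], []
    for res in (run.tumor, run.control):
        if res is not None and res.estimate.is_defined:
            samples.append(res.sample)
            values.append(res.estimate.trpm)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.bar(samples, values, color=["#c0392b", "#2980b9"][: len(samples)])
    ax.set_ylabel("telomere content (TRPM)")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_repeats_histogram(run: "RunResult", path: str) -> None:
    fig, ax = plt.subplots(figsize=(5, 4))
    for res in (run.tumor, run.control):
        if res is None or not res.repeats_histogram:
            continue
        xs = sorted(res.repeats_histogram)
        ys = [res.repeats_histogram[x] for x in xs]
        ax.plot(xs, ys, marker="o", label=res.sample)
    ax.set_xlabel("repeat units per intratelomeric read")
    ax.set_ylabel("reads")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def _plot_log2_panel(table, path: str, title: str) -> None:
    if "log2_tc" not in table.columns or table.empty:
        return
    sub = table.dropna(subset=["log2_tc"])
    if sub.empty:
        return
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.bar(sub["hexamer"], sub["log2_tc"], color="#8e44ad")
    ax.axhline(0, color="black", linewidth=0.8)
    ax.set_ylabel("log2 T/C")
    ax.set_title(title)
    plt.setp(ax.get_xticklabels(), rotation=45, ha="right")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_spectrum(run: "RunResult", path: str) -> None:
    fig, axes = plt.subplots(
        1, 2 if run.control is not None else 1, figsize=(9, 4), squeeze=False
    )
    for ax, res in zip(axes[0], (run.tumor, run.control)):
        if res is None:
            continue
        spectrum = res.spectrum.set_index("chromosome")
        spectrum.plot.bar(stacked=True, ax=ax, legend=False)
        ax.set_title(res.sample)
        ax.set_ylabel("telomeric reads")
    axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def plot_all(run: "RunResult", out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    plot_content_bar(run, os.path.join(out_dir, "telomere_content.png"))
    plot_repeats_histogram(run, os.path.join(out_dir, "repeats_per_read.png"))
    _plot_log2_panel(
        run.profile.hexamer_table, os.path.join(out_dir, "tvr_log2.png"),
        "TVRs (arbitrary context)",
    )
    _plot_log2_panel(
        run.profile.singleton_table, os.path.join(out_dir, "singleton_log2.png"),
        "Singleton TVRs",
    )
    plot_spectrum(run, os.path.join(out_dir, "spectrum.png"))
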