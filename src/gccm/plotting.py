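"""Tile plot of longitudinal concordance: one row per patient, x = days
from admission, epoch segments colored by concordance class (or by the
final care-received category), with dashes marking individual
goals-of-care discussions."""

from __future__ import annotations

from typing import Optional

import matplotlib

matplotlib.use("Agg")
matplotlib.rcParams["svg.hashsalt"] = "gccm"  # byte-stable SVG element ids
import matplotlib.pyplot as plt
from matplotlib.patches import Patch

from .cohort import CohortBundle, ValidationError
from .concordance import ConcordanceRecord

CONCORDANCE_COLORS = {
    "concordant": "#2b8cbe",
    "discordant": "#e34a33",
    "uncertain": "#bdbdbd",
}
CARE_COLORS = {
    "comfort_focused": "#31a354",
    "maintain_improve_function": "#756bb1",
    "life_extension": "#e6550d",
    "unclear": "#bdbdbd",
}


def tile_plot(
    records,
    epochs_by_patient: dict,
    bundle: CohortBundle,
    out_path=None,
    color_by: str = "concordance",
    final_calls=None,
    figsize=None,
):
    """Render the cohort's longitudinal concordance as stacked tiles.

    Patients are ordered by descending epoch count then id (documented,
    deterministic). Saving to an SVG path gives byte-stable output for
    fixed inputs. Returns the matplotlib figure.
    """
    if not bundle.patients:
        raise ValidationError("cannot plot an empty cohort")
    if color_by == "concordance":
        colors = CONCORDANCE_COLORS
        key = {(r.patient_id, r.epoch_index): r.concordance.value for r in records}
    elif color_by == "care":
        if final_calls is None:
            raise ValidationError("color_by='care' requires final_calls")
        colors = CARE_COLORS
        key = {(c.patient_id, c.epoch_index): c.category.value for c in final_calls}
    else:
        raise ValueError(f"unknown color_by {color_by!r}")

    order = sorted(
        bundle.patients,
        key=lambda pid: (-len(epochs_by_patient[pid]), pid),
    )
    fig, ax = plt.subplots(
        figsize=figsize or (8, max(2.0, 0.18 * len(order) + 1.0))
    )
    for y, pid in enumerate(order):
        adm = bundle.patients[pid].admission_date
        for e in epochs_by_patient[pid]:
            x0 = (e.start_date - adm).days
            x1 = (e.end_date - adm).days
            ax.barh(y, x1 - x0, left=x0, height=0.85,
                    color=colors[key[(pid, e.epoch_index)]],
                    edgecolor="white", linewidth=0.3)
        for d in bundle.discussions_for(pid):
            x = (d.discussion_date - adm).days
            if x >= 0:
                ax.plot([x, x], [y - 0.42, y + 0.42], color="black",
                        linewidth=0.8, solid_capstyle="butt")
    ax.set_xlabel("Days from admission")
    ax.set_ylabel("Patients")
    ax.set_yticks([])
    ax.set_ylim(-0.6, len(order) - 0.4)
    ax.invert_yaxis()
    ax.legend(
        handles=[Patch(color=c, label=lab.replace("_", " ")) for lab, c in colors.items()],
        loc="upper right", fontsize=7, frameon=False,
    )
    fig.tight_layout()
    if out_path is not None:
        fig.savefig(out_path, metadata={"Date": None} if str(out_path).endswith(".svg") else None)
        plt.close(fig)
    return fig
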