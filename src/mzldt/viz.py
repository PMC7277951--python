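"""Pathway-names-cloud rendering.

Overrepresented pathways are drawn as text whose font size grows
monotonically with the representation score (default: proportional to the
square root of the score, so a 4x score doubles the font).  The five
top-scoring pathways are highlighted in red; a fixed-size reference marker
is drawn in the corner so clouds from different subjects can be compared at
a glance.  Words are placed on a seeded Archimedean spiral with
bounding-box collision avoidance, so output is deterministic for a given
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import matplotlib
import numpy as np
import pandas as pd

matplotlib.use("Agg")
import matplotlib.pyplot as plt

SIZE_MAPS = ("sqrt", "log", "linear")


@dataclass(frozen=True)
class CloudSpec:
    """Layout parameters for the names cloud."""

    size_map: str = "sqrt"
    top_k_highlight: int = 5
    max_font: float = 44.0
    display_floor: float = 1.0     # scores at or below the null expectation are not drawn
    width: float = 10.0            # inches
    height: float = 7.0
    highlight_color: str = "#cc0000"
    base_color: str = "#333333"
    reference_score: float = 10.0  # score of the constant comparison marker

    def __post_init__(self) -> None:
        if self.size_map not in SIZE_MAPS:
            raise ValueError(f"size_map must be one of {SIZE_MAPS}")
        if self.max_font <= 0:
            raise ValueError("max_font must be positive")


def font_size(score: float, max_score: float, spec: CloudSpec) -> float:
    """Monotone score → font-size map; never inverts score order.

    "sqrt" is proportional to sqrt(score) (scores 1 and 4 give a 1:2 font
    ratio), "linear" to the score, "log" to log1p(score).
    """
    if score < 0 or max_score <= 0:
        raise ValueError("scores must be non-negative with a positive maximum")
    if spec.size_map == "sqrt":
        frac = math.sqrt(score) / math.sqrt(max_score)
    elif spec.size_map == "linear":
        frac = score / max_score
    else:
        frac = math.log1p(score) / math.log1p(max_score)
    return spec.max_font * frac


def _estimate_bbox(text: str, size_pt: float) -> tuple[float, float]:
    """Rough text extent in points (monospace-ish heuristic; layout only)."""
    return 0.58 * size_pt * max(len(text), 1), 1.25 * size_pt


def _spiral_place(
    boxes: list[tuple[float, float]],
    canvas_w: float,
    canvas_h: float,
    rng: np.random.Generator,
) -> list[tuple[float, float]]:
    """Greedy spiral placement of (w, h) boxes on a canvas, center first."""
    placed: list[tuple[float, float, float, float]] = []
    centers: list[tuple[float, float]] = []
    cx, cy = canvas_w / 2, canvas_h / 2
    for w, h in boxes:
        theta0 = rng.uniform(0, 2 * math.pi)
        pos = None
        t = 0.0
        while t < 220:
            r = 3.0 * t
            x = cx + r * math.cos(theta0 + 0.55 * t) - w / 2
            y = cy + r * math.sin(theta0 + 0.55 * t) - h / 2
            rect = (x, y, x + w, y + h)
            inside = 0 <= rect[0] and rect[2] <= canvas_w and 0 <= rect[1] and rect[3] <= canvas_h
            clash = any(
                not (rect[2] <= a or rect[0] >= c or rect[3] <= b or rect[1] >= d)
                for a, b, c, d in placed
            )
            if inside and not clash:
                pos = rect
                break
            t += 0.7
        if pos is None:  # give up on collision-freedom, keep the word visible
            pos = (
                min(max(cx - w / 2, 0), canvas_w - w),
                min(max(cy - h / 2, 0), canvas_h - h),
                0,
                0,
            )
            pos = (pos[0], pos[1], pos[0] + w, pos[1] + h)
        placed.append(pos)
        centers.append(((pos[0] + pos[2]) / 2, (pos[1] + pos[3]) / 2))
    return centers


def render_cloud(
    profile: pd.DataFrame,
    spec: CloudSpec | None = None,
    path: str = "cloud.svg",
    seed: int = 0,
) -> pd.DataFrame:
    """Render a score profile as a pathway-names cloud (SVG/PNG by extension).

    Every pathway scoring above ``spec.display_floor`` appears exactly once,
    largest scores first (center of the spiral).  Returns the drawn entries
    (name, score, font size, color).  All-zero or empty profiles produce an
    empty-state image with a message.
    """
    spec = spec or CloudSpec()
    rng = np.random.default_rng(seed)
    with matplotlib.rc_context({"svg.hashsalt": str(seed)}):
        fig, ax = plt.subplots(figsize=(spec.width, spec.height))
        ax.set_axis_off()
        canvas_w, canvas_h = spec.width * 72, spec.height * 72
        ax.set_xlim(0, canvas_w)
        ax.set_ylim(0, canvas_h)

        shown = profile[profile["score"] > spec.display_floor]
        shown = shown.sort_values(["score", "pathway_name"], ascending=[False, True], kind="stable")
        if len(shown) == 0:
            ax.text(
                canvas_w / 2, canvas_h / 2,
                "no overrepresented pathways",
                ha="center", va="center", fontsize=18, color="#777777",
            )
            fig.savefig(path, metadata={"Date": None} if path.endswith(".svg") else None)
            plt.close(fig)
            return pd.DataFrame(columns=["pathway_name", "score", "font_size", "color"])

        max_score = float(shown["score"].max())
        entries = []
        for rank, (_, row) in enumerate(shown.iterrows()):
            size = font_size(float(row["score"]), max_score, spec)
            color = spec.highlight_color if rank < spec.top_k_highlight else spec.base_color
            entries.append((str(row["pathway_name"]), float(row["score"]), size, color))

        boxes = [_estimate_bbox(name, size) for name, _, size, _ in entries]
        centers = _spiral_place(boxes, canvas_w, canvas_h, rng)
        for (name, _, size, color), (x, y) in zip(entries, centers):
            ax.text(x, y, name, ha="center", va="center", fontsize=size, color=color)

        # constant-size reference marker for cross-plot comparison
        ref_size = font_size(spec.reference_score, spec.reference_score, spec) * 0.5
        ax.text(6, 10, "[×]", fontsize=ref_size, color="#1f77b4", ha="left", va="bottom")
        ax.text(6 + 2.2 * ref_size, 10, f"reference (score {spec.reference_score:g})",
                fontsize=9, color="#1f77b4", ha="left", va="bottom")

        fig.savefig(path, metadata={"Date": None} if path.endswith(".svg") else None)
        plt.close(fig)
    return pd.DataFrame(entries, columns=["pathway_name", "score", "font_size", "color"])
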