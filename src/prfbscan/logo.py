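"""Position-frequency matrices and information content for motif windows.

The math behind a nucleotide sequence logo: anchor-aligned stacking of
(possibly clipped, unequal-length) windows into per-position base counts,
plug-in frequencies, and Shannon information in bits against a background,
``I(j) = log2(4) + sum_b f_b log2 f_b`` for the uniform background (0 log 0
taken as 0), so a fully conserved position carries 2 bits and a uniform one
0 bits.  A small-sample correction is available behind a flag but off by
default.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence, Tuple

import numpy as np
import pandas as pd

__all__ = ["LogoMatrix", "build_logo", "consensus", "plot_logo"]

ALPHABET = "ACGT"
_IDX = {b: i for i, b in enumerate(ALPHABET)}


@dataclass
class LogoMatrix:
    """Per-position counts, frequencies and information of aligned windows.

    ``counts`` is (n_positions, 4) over A,C,G,T; ``coverage`` counts how many
    windows contributed a base at each position (clipped windows contribute
    nothing outside their extent, as do N characters).  ``anchor_position``
    records which matrix position the window anchors (stop starts) map to.
    """

    counts: np.ndarray
    coverage: np.ndarray
    anchor_position: int
    background: np.ndarray
    small_sample_correction: bool = False

    @property
    def n_positions(self) -> int:
        return self.counts.shape[0]

    @property
    def freqs(self) -> np.ndarray:
        cov = np.where(self.coverage > 0, self.coverage, 1)
        return self.counts / cov[:, None]

    @property
    def info_bits(self) -> np.ndarray:
        """Per-position information in bits, in [0, 2] for a uniform background."""
        f = self.freqs
        with np.errstate(divide="ignore", invalid="ignore"):
            if np.allclose(self.background, 0.25):
                terms = np.where(f > 0, f * np.log2(np.where(f > 0, f, 1.0)), 0.0)
                info = 2.0 + terms.sum(axis=1)
            else:  # relative entropy against a non-uniform background
                ratio = np.where(f > 0, f / self.background[None, :], 1.0)
                info = (np.where(f > 0, f, 0.0) * np.log2(ratio)).sum(axis=1)
        if self.small_sample_correction:
            n = np.where(self.coverage > 0, self.coverage, 1)
            info = info - 3.0 / (2.0 * np.log(2) * n)
        info = np.where(self.coverage > 0, np.clip(info, 0.0, None), 0.0)
        return info

    def to_dataframe(self) -> pd.DataFrame:
        df = pd.DataFrame(self.counts, columns=[f"count_{b}" for b in ALPHABET])
        df.insert(0, "position", np.arange(self.n_positions) - self.anchor_position)
        df["coverage"] = self.coverage
        for i, b in enumerate(ALPHABET):
            df[f"freq_{b}"] = self.freqs[:, i]
        df["info_bits"] = self.info_bits
        return df

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False, float_format="%.6g")

    def write_json(self, path) -> None:
        payload = {
            "alphabet": list(ALPHABET),
            "anchor_position": int(self.anchor_position),
            "background": [float(b) for b in self.background],
            "counts": self.counts.astype(int).tolist(),
            "coverage": self.coverage.astype(int).tolist(),
            "freqs": np.round(self.freqs, 10).tolist(),
            "info_bits": np.round(self.info_bits, 10).tolist(),
            "consensus": consensus(self),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def build_logo(
    windows: Sequence[Tuple[str, int]],
    width: int,
    anchor_position: Optional[int] = None,
    background: Optional[Sequence[float]] = None,
    small_sample_correction: bool = False,
) -> LogoMatrix:
    """Stack anchor-aligned windows into a :class:`LogoMatrix`.

    Each window is a ``(sequence, anchor_offset)`` pair where the anchor
    offset marks the stop start within the sequence, so unequal-length and
    clipped windows align correctly.  ``anchor_position`` fixes where the
    anchor lands in the matrix (default: the largest anchor offset seen, so
    every window fits on the left).
    """
    windows = list(windows)
    if not windows:
        raise ValueError("empty window list")
    if width <= 0:
        raise ValueError("width must be positive")
    if background is None:
        bg = np.full(4, 0.25)
    else:
        bg = np.asarray(background, dtype=float)
        if bg.shape != (4,) or abs(bg.sum() - 1.0) > 1e-9 or (bg < 0).any():
            raise ValueError("background must be 4 non-negative values summing to 1")
    if anchor_position is None:
        anchor_position = max(a for _, a in windows)

    counts = np.zeros((width, 4), dtype=np.int64)
    for seq, anchor in windows:
        s = seq.upper()
        for j in range(width):
            idx = anchor + (j - anchor_position)
            if 0 <= idx < len(s):
                b = _IDX.get(s[idx])
                if b is not None:
                    counts[j, b] += 1
    return LogoMatrix(
        counts=counts,
        coverage=counts.sum(axis=1),
        anchor_position=anchor_position,
        background=bg,
        small_sample_correction=small_sample_correction,
    )


def consensus(matrix: LogoMatrix, tie_char: str = "N") -> str:
    """Most frequent base per position; exact ties -> ``tie_char``; no coverage -> '.'."""
    out = []
    for j in range(matrix.n_positions):
        if matrix.coverage[j] == 0:
            out.append(".")
            continue
        row = matrix.counts[j]
        top = row.max()
        winners = [ALPHABET[i] for i in range(4) if row[i] == top]
        out.append(winners[0] if len(winners) == 1 else tie_char)
    return "".join(out)


def plot_logo(matrix: LogoMatrix, ax=None, title: Optional[str] = None):
    """Minimal information-scaled stacked-bar rendering of the matrix.

    Cosmetic only; the quantitative surface is the matrix itself.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(max(4, matrix.n_positions * 0.4), 2.5))
    colors = {"A": "#2ca02c", "C": "#1f77b4", "G": "#ff7f0e", "T": "#d62728"}
    freqs = matrix.freqs
    info = matrix.info_bits
    xs = np.arange(matrix.n_positions) - matrix.anchor_position
    for j in range(matrix.n_positions):
        order = np.argsort(freqs[j])  # tallest letter on top
        bottom = 0.0
        for i in order:
            h = freqs[j, i] * info[j]
            if h <= 0:
                continue
            ax.bar(xs[j], h, bottom=bottom, width=0.85,
                   color=colors[ALPHABET[i]], edgecolor="none")
            bottom += h
    ax.set_ylim(0, 2)
    ax.set_ylabel("bits")
    ax.set_xlabel("position relative to premature-stop start")
    if title:
        ax.set_title(title)
    return ax
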