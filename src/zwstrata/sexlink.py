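"""Coverage-based sex-linkage classification of scaffolds.

In a ZW female the W chromosome and the differentiated part of the Z are
present in one copy, so female read depth over those scaffolds sits at half
the autosomal level. W candidates are scaffolds at half coverage that do NOT
align extensively to the reference Z; scaffolds mostly covered by reference-Z
alignments are Z-linked regardless of depth.

Depth input follows the samtools-depth dialect (1-based positions, zero-depth
positions typically absent). Window coordinates and all emitted intervals are
0-based half-open.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

LABEL_W = "W_candidate"
LABEL_Z = "Z_linked"
LABEL_A = "autosomal"
LABEL_U = "unclassified"


@dataclass
class DepthTrack:
    scaffold_id: str
    positions: np.ndarray  # 1-based, strictly increasing
    depth: np.ndarray

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.depth = np.asarray(self.depth, dtype=np.int64)
        if self.positions.size != self.depth.size:
            raise ValueError("positions/depth length mismatch")
        if self.positions.size and (
            self.positions[0] < 1 or np.any(np.diff(self.positions) <= 0)
        ):
            raise ValueError(f"{self.scaffold_id}: positions must be strictly increasing, 1-based")


@dataclass(frozen=True)
class WindowStat:
    scaffold_id: str
    start: int  # 0-based half-open
    end: int
    covered_bases: int
    mean_depth: float


@dataclass(frozen=True)
class ScaffoldCall:
    scaffold_id: str
    relative_depth: float  # nan when no retained window
    z_aligned_fraction: float
    label: str


def window_depth(
    track: DepthTrack,
    window_size: int = 50_000,
    min_covered: int = 30_000,
    step: int | None = None,
) -> list[WindowStat]:
    """Mean depth over tiled windows, dropping poorly covered windows.

    A position counts as covered when its depth is positive; windows with
    fewer than ``min_covered`` covered bases are removed. ``mean_depth``
    averages over covered positions only.
    """
    if window_size <= 0:
        raise ValueError("window_size must be positive")
    if min_covered > window_size:
        raise ValueError("min_covered cannot exceed window_size")
    step = window_size if step is None else step
    if track.positions.size == 0:
        return []
    pos0 = track.positions - 1  # to 0-based
    covered_mask = track.depth > 0
    last = int(pos0[-1])
    out: list[WindowStat] = []
    for start in range(0, last + 1, step):
        end = start + window_size
        lo = np.searchsorted(pos0, start, side="left")
        hi = np.searchsorted(pos0, end, side="left")
        cov = int(covered_mask[lo:hi].sum())
        if cov < min_covered:
            continue
        total = int(track.depth[lo:hi][covered_mask[lo:hi]].sum())
        out.append(WindowStat(track.scaffold_id, start, end, cov, total / cov))
    return out


def autosomal_baseline(window_stats: Sequence[WindowStat]) -> float:
    """Median retained-window depth: the autosomal coverage level.

    In a realistic genome the bulk of retained windows are autosomal, so the
    median is robust to the half-coverage sex-linked minority.
    """
    if not window_stats:
        raise ValueError("no retained windows; cannot estimate baseline")
    return float(np.median([w.mean_depth for w in window_stats]))


def z_aligned_fraction(
    scaffold_length: int, blocks: Sequence[tuple[int, int]]
) -> float:
    """Fraction of a scaffold covered by reference-Z alignments (union)."""
    if scaffold_length <= 0:
        raise ValueError("scaffold_length must be positive")
    merged_total = 0
    cur_s = cur_e = None
    for s, e in sorted(blocks):
        if s < 0 or e > scaffold_length or e <= s:
            raise ValueError(f"alignment block [{s}, {e}) outside scaffold bounds")
        if cur_s is None:
            cur_s, cur_e = s, e
        elif s <= cur_e:
            cur_e = max(cur_e, e)
        else:
            merged_total += cur_e - cur_s
            cur_s, cur_e = s, e
    if cur_s is not None:
        merged_total += cur_e - cur_s
    return merged_total / scaffold_length


def classify_scaffold(
    windows: Sequence[WindowStat],
    baseline: float,
    z_aligned_frac: float = 0.0,
    half_band: tuple[float, float] = (0.35, 0.65),
    z_threshold: float = 0.60,
) -> ScaffoldCall:
    """Label one scaffold W-candidate / Z-linked / autosomal.

    Z-alignment takes precedence (a mostly-Z-aligned scaffold is Z-linked
    whatever its depth, and in a female the differentiated Z also sits at
    half coverage); then the half-coverage band selects W candidates among
    the rest.
    """
    if baseline <= 0:
        raise ValueError("baseline must be positive")
    if not windows:
        sid = "?"
        return ScaffoldCall(sid, float("nan"), z_aligned_frac, LABEL_U)
    sid = windows[0].scaffold_id
    weights = np.array([w.covered_bases for w in windows], dtype=float)
    means = np.array([w.mean_depth for w in windows])
    rel = float((means * weights).sum() / weights.sum() / baseline)
    if z_aligned_frac > z_threshold:
        label = LABEL_Z
    elif half_band[0] <= rel <= half_band[1]:
        label = LABEL_W
    elif rel >= half_band[1]:
        label = LABEL_A
    else:
        label = LABEL_U
    return ScaffoldCall(sid, rel, z_aligned_frac, label)


def classify_genome(
    tracks: dict[str, DepthTrack],
    z_blocks: dict[str, Sequence[tuple[int, int]]],
    scaffold_lengths: dict[str, int],
    window_size: int = 50_000,
    min_covered: int = 30_000,
    half_band: tuple[float, float] = (0.35, 0.65),
    z_threshold: float = 0.60,
) -> list[ScaffoldCall]:
    """Whole-genome classification: windows, shared baseline, per-scaffold calls."""
    per_scaffold = {
        sid: window_depth(t, window_size=window_size, min_covered=min_covered)
        for sid, t in tracks.items()
    }
    all_windows = [w for ws in per_scaffold.values() for w in ws]
    baseline = autosomal_baseline(all_windows)
    calls = []
    for sid, ws in per_scaffold.items():
        frac = z_aligned_fraction(scaffold_lengths[sid], z_blocks.get(sid, []))
        call = classify_scaffold(ws, baseline, frac, half_band, z_threshold)
        if not ws:
            call = ScaffoldCall(sid, float("nan"), frac, LABEL_U)
        calls.append(call)
    return calls
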