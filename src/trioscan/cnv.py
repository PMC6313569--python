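"""Depth-based CNV detection via circular binary segmentation (CBS).

The segmenter maximizes the two-sample t-statistic over all arc splits of
the circularized bin sequence, accepts a split when its seeded permutation
p-value is below ``alpha``, and recurses on the resulting sub-segments.
Segmentation runs on linear normalized depth (a homozygous deletion sits at
0, where a log-ratio would be undefined).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

DEFAULT_ALPHA = 0.01
DEFAULT_N_PERMUTATIONS = 1000
DEFAULT_MIN_WIDTH = 3

SAMPLES = ("father", "mother", "proband")

#: Copy-state thresholds on mean normalized depth.
HOM_DEL_MAX = 0.25
HEMI_MAX = 0.75
NORMAL_MAX = 1.25


@dataclass
class Segment:
    contig: str
    start: int  # 0-based half-open, in bp
    end: int
    mean_depth: dict[str, float]
    copy_state: dict[str, str]

    @property
    def length(self) -> int:
        return self.end - self.start


def normalize_depth(raw: pd.DataFrame) -> pd.DataFrame:
    """Divide each sample's depth column by its median raw depth.

    By construction the per-sample median normalized depth is exactly 1.
    """
    out = raw.copy()
    for col in ("depth_father", "depth_mother", "depth_proband"):
        med = float(raw[col].median())
        if med <= 0:
            raise ValueError(f"{col}: non-positive median depth")
        out[col] = raw[col] / med
    return out


def _max_t(x: np.ndarray, min_width: int) -> tuple[float, int, int]:
    """Maximal |t| over all arcs x[i:j] vs their (wrapping) complement.

    Arcs and complements are symmetric under the two-sample statistic, so
    scanning non-wrapping arcs covers the circularized search. Returns
    (t, i, j); t = 0 with i = j = -1 when no admissible split exists.
    """
    n = x.size
    s0 = float(x.std())
    if n < 2 * min_width or s0 == 0.0:
        return 0.0, -1, -1
    S = np.empty(n + 1)
    S[0] = 0.0
    np.cumsum(x, out=S[1:])
    tot = S[-1]
    best = 0.0
    bi = bj = -1
    for m in range(min_width, n - min_width + 1):
        w = 1.0 / m + 1.0 / (n - m)
        sums = S[m:] - S[: n - m + 1]
        t = np.abs(sums * w - tot / (n - m)) / (s0 * np.sqrt(w))
        k = int(np.argmax(t))
        if t[k] > best:
            best = float(t[k])
            bi, bj = k, k + m
    return best, bi, bj


def _split_significant(
    x: np.ndarray,
    t_obs: float,
    alpha: float,
    n_permutations: int,
    min_width: int,
    rng: np.random.Generator,
    block: int = 100,
) -> bool:
    """Seeded permutation test with sequential early stopping.

    Stops rejecting as soon as the exceedance count can no longer yield
    p < alpha; stops accepting once the running estimate (e+1)/(done+1)
    falls below alpha. Running all ``n_permutations`` decides by e/n < alpha.
    """
    reject_at = int(np.ceil(alpha * n_permutations))  # e ≥ this ⇒ p ≥ alpha
    exceed = 0
    done = 0
    while done < n_permutations:
        todo = min(block, n_permutations - done)
        for _ in range(todo):
            t_perm, _, _ = _max_t(rng.permutation(x), min_width)
            if t_perm >= t_obs:
                exceed += 1
        done += todo
        if exceed >= reject_at:
            return False
        if (exceed + 1) / (done + 1) < alpha:
            return True
    return exceed / n_permutations < alpha


def segment_cbs(
    values: Sequence[float],
    alpha: float = DEFAULT_ALPHA,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    min_width: int = DEFAULT_MIN_WIDTH,
    rng: Optional[np.random.Generator] = None,
) -> list[int]:
    """Changepoint indices (sorted, interior) of an ordered value sequence.

    A changepoint at index k separates bins [.., k-1] from [k, ..]. Input
    shorter than 2·min_width yields a single segment (no changepoints).
    """
    x = np.asarray(values, dtype=float)
    if rng is None:
        rng = np.random.default_rng(0)
    changepoints: list[int] = []

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        t_obs, i, j = _max_t(seg, min_width)
        if i < 0:
            return
        if not _split_significant(seg, t_obs, alpha, n_permutations, min_width, rng):
            return
        cuts = [c for c in (i, j) if 0 < c < hi - lo]
        for c in cuts:
            changepoints.append(lo + c)
        for a, b in zip([lo] + [lo + c for c in cuts], [lo + c for c in cuts] + [hi]):
            if b - a < hi - lo:  # progress guard
                recurse(a, b)

    recurse(0, x.size)
    return sorted(changepoints)


def _state(mean: float) -> str:
    if mean < HOM_DEL_MAX:
        return "hom_del"
    if mean < HEMI_MAX:
        return "hemi"
    if mean < NORMAL_MAX:
        return "normal"
    return "gain"


def call_copy_states(
    bins: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    n_permutations: int = DEFAULT_N_PERMUTATIONS,
    min_width: int = DEFAULT_MIN_WIDTH,
    seed: int = 0,
    samples: Sequence[str] = SAMPLES,
) -> list[Segment]:
    """Segment every sample per contig, merge changepoints across the trio,
    and call a copy state per sample on each consensus segment.

    ``bins`` is a normalized depth table (see :func:`normalize_depth`) on a
    bin grid shared by the three samples.
    """
    segments: list[Segment] = []
    rng = np.random.default_rng(seed)
    for contig, sub in bins.groupby("contig", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        cuts: set[int] = set()
        for sample in samples:
            vals = sub[f"depth_{sample}"].to_numpy()
            cuts.update(
                segment_cbs(
                    vals,
                    alpha=alpha,
                    n_permutations=n_permutations,
                    min_width=min_width,
                    rng=rng,
                )
            )
        bounds = [0] + sorted(cuts) + [len(sub)]
        for a, b in zip(bounds, bounds[1:]):
            means = {
                sample: float(sub[f"depth_{sample}"].iloc[a:b].mean())
                for sample in samples
            }
            segments.append(
                Segment(
                    contig=str(contig),
                    start=int(sub["start"].iloc[a]),
                    end=int(sub["end"].iloc[b - 1]),
                    mean_depth=means,
                    copy_state={s: _state(m) for s, m in means.items()},
                )
            )
    return segments


def classify_inheritance(
    segment: Segment,
    father: str = "father",
    mother: str = "mother",
    proband: str = "proband",
) -> str:
    """Explicit trio rule replacing manual de novo CNV review:

    child hom_del with both parents hemizygous → inherited_recessive;
    child copy loss with both parents normal → de_novo; anything else → other.
    """
    child = segment.copy_state[proband]
    pf = segment.copy_state[father]
    pm = segment.copy_state[mother]
    if child == "hom_del" and pf == "hemi" and pm == "hemi":
        return "inherited_recessive"
    if child in ("hom_del", "hemi") and pf == "normal" and pm == "normal":
        return "de_novo"
    return "other"


def segments_to_frame(segments: Sequence[Segment]) -> pd.DataFrame:
    rows = []
    for seg in segments:
        row: dict[str, object] = {
            "contig": seg.contig,
            "start": seg.start,
            "end": seg.end,
        }
        for s in SAMPLES:
            row[f"mean_{s}"] = round(seg.mean_depth[s], 4)
            row[f"state_{s}"] = seg.copy_state[s]
        row["inheritance"] = classify_inheritance(seg)
        rows.append(row)
    return pd.DataFrame(rows)
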