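"""Linear B-cell epitope panel and consensus-vote region calling.

The panel replaces webserver ensembles with seven classical per-residue
propensity scales (hydrophilicity, surface accessibility, flexibility,
antigenicity, turn propensity, polarity, exposure).  Each scale produces a
windowed per-residue statistic, a z-normalized profile and a binary call;
residues called by at least ``min_votes`` scales (default: the >=5-of-8
consensus rule rescaled to the panel size) are merged into maximal runs and
runs shorter than ``min_region_length`` are discarded.

The consensus machinery is deliberately value-agnostic: the voting rule,
not any single scale, is the contract.  Regions predicted by trained
webserver ensembles (e.g. the published consensus regions for the legume
LTP queries) are loaded from packaged fixtures via
:func:`load_reported_epitopes` for downstream overlap and PD analysis.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .residues import AMINO_ACIDS


def _load_scale_registry() -> dict[str, dict]:
    with resources.files("ltp_epimap.data").joinpath("propensity_scales.json").open() as fh:
        registry = json.load(fh)
    registry.pop("_notes", None)
    return registry


SCALE_REGISTRY: dict[str, dict] = _load_scale_registry()
DEFAULT_SCALES: tuple[str, ...] = tuple(SCALE_REGISTRY)


@dataclass(frozen=True)
class PropensityProfile:
    """Per-residue profile of one propensity scale over one sequence."""

    scale: str
    window: int
    raw: tuple[float, ...]
    z: tuple[float, ...]
    calls: tuple[bool, ...]

    def __post_init__(self) -> None:
        if not (len(self.raw) == len(self.z) == len(self.calls)):
            raise ValueError("profile arrays must have equal length")


@dataclass(frozen=True)
class EpitopeRegion:
    """A contiguous predicted or validated epitope (1-based inclusive coords)."""

    parent_id: str
    start: int
    end: int
    sequence: str
    kind: str = "linear"
    votes: int | None = None
    epitope_index: int | None = None
    note: str = ""

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad coordinates {self.start}-{self.end}")
        if not self.sequence:
            raise ValueError("empty epitope sequence")

    def __len__(self) -> int:
        return len(self.sequence)


def scale_profile(seq: str, scale: str, window: int = 7) -> PropensityProfile:
    """Windowed propensity profile with z-normalization and binary calls.

    Windows are symmetric and truncated at the termini.  The windowed
    statistic is the arithmetic mean, except the accessibility scale which
    uses its published product form (per-position values divided by the 0.37
    mean surface probability, multiplied over the window).  Calls are
    ``z > 0`` by default; the antigenicity scale keeps its published
    absolute rule (windowed mean propensity > 1.0).  A zero-variance profile
    yields no calls (z-score undefined, conservative).
    """
    if scale not in SCALE_REGISTRY:
        raise KeyError(f"unknown scale {scale!r}; available: {sorted(SCALE_REGISTRY)}")
    if window < 1 or window % 2 == 0:
        raise ValueError("window must be a positive odd integer")
    if not seq:
        raise ValueError("empty sequence")
    if window > len(seq):
        raise ValueError(f"window {window} exceeds sequence length {len(seq)}")
    bad = set(seq) - set(AMINO_ACIDS)
    if bad:
        raise ValueError(f"illegal residue(s) {sorted(bad)}")

    spec = SCALE_REGISTRY[scale]
    values = np.array([spec["values"][ch] for ch in seq])
    half = window // 2
    raw = np.empty(len(seq))
    for i in range(len(seq)):
        win = values[max(0, i - half) : i + half + 1]
        if spec["statistic"] == "product":
            raw[i] = np.prod(win / spec.get("normalizer", 1.0))
        else:
            raw[i] = win.mean()

    sd = raw.std()
    if sd <= 1e-12 * max(1.0, float(np.abs(raw).max())):  # constant profile
        z = np.zeros_like(raw)
        calls = np.zeros(len(seq), dtype=bool)
    else:
        z = (raw - raw.mean()) / sd
        if spec["call_rule"] == "absolute":
            calls = raw > spec["threshold"]
        else:
            calls = z > 0.0
    return PropensityProfile(
        scale=scale,
        window=window,
        raw=tuple(float(x) for x in raw),
        z=tuple(float(x) for x in z),
        calls=tuple(bool(c) for c in calls),
    )


def panel_profiles(
    seq: str, scales: Sequence[str] = DEFAULT_SCALES, window: int = 7
) -> list[PropensityProfile]:
    return [scale_profile(seq, s, window) for s in scales]


def default_min_votes(n_predictors: int) -> int:
    """Rescale the >=5-of-8 webserver consensus rule to a panel of any size."""
    return math.ceil(5 * n_predictors / 8)


def consensus_regions(
    seq: str,
    profiles: Sequence[PropensityProfile],
    parent_id: str = "query",
    min_votes: int | None = None,
    min_region_length: int = 6,
    weights: Sequence[float] | None = None,
) -> list[EpitopeRegion]:
    """Merge per-scale calls into consensus epitope regions.

    Per-residue votes are the (optionally weighted) number of calling
    profiles; residues with votes >= ``min_votes`` form maximal runs, and
    runs shorter than ``min_region_length`` are dropped.  Weights default to
    1.0 each — they exist to de-emphasize low-performing predictors without
    changing the voting rule.
    """
    if not profiles:
        raise ValueError("need at least one profile")
    lengths = {len(p.calls) for p in profiles}
    if lengths != {len(seq)}:
        raise ValueError(f"profile lengths {sorted(lengths)} do not match sequence {len(seq)}")
    if weights is None:
        weights = [1.0] * len(profiles)
    if len(weights) != len(profiles):
        raise ValueError("one weight per profile required")
    if min_votes is None:
        min_votes = default_min_votes(len(profiles))
    if min_votes > sum(weights):
        raise ValueError("min_votes exceeds the attainable weighted vote count")

    votes = np.zeros(len(seq))
    for profile, w in zip(profiles, weights):
        votes += w * np.array(profile.calls)

    regions: list[EpitopeRegion] = []
    i = 0
    while i < len(seq):
        if votes[i] >= min_votes:
            j = i
            while j + 1 < len(seq) and votes[j + 1] >= min_votes:
                j += 1
            if j - i + 1 >= min_region_length:
                regions.append(
                    EpitopeRegion(
                        parent_id=parent_id,
                        start=i + 1,
                        end=j + 1,
                        sequence=seq[i : j + 1],
                        kind="linear",
                        votes=int(votes[i : j + 1].max()),
                    )
                )
            i = j + 1
        else:
            i += 1
    return regions


def vote_counts(seq: str, profiles: Sequence[PropensityProfile]) -> np.ndarray:
    """Unweighted per-residue vote counts across profiles."""
    lengths = {len(p.calls) for p in profiles}
    if lengths != {len(seq)}:
        raise ValueError("profile lengths do not match sequence")
    return np.sum([p.calls for p in profiles], axis=0)


def load_reported_epitopes(source: str | Path = "table2") -> list[EpitopeRegion]:
    """Load packaged (or user) epitope-region fixtures.

    ``source`` is ``"table2"`` (the consensus regions reported for the five
    legume LTP queries), ``"validated"`` (the three experimentally mapped
    peach epitopes) or a path to a TSV with the same columns.  Rows whose
    residue-string length disagrees with the coordinate span are accepted
    only when the row carries a note recording the discrepancy — the string
    is authoritative; silent guessing is an error.
    """
    if source == "table2":
        handle = resources.files("ltp_epimap.data").joinpath("table2_epitopes.tsv")
    elif source == "validated":
        handle = resources.files("ltp_epimap.data").joinpath("peach_validated_epitopes.tsv")
    else:
        handle = Path(source)
    with (handle.open() if hasattr(handle, "open") else open(handle)) as fh:
        frame = pd.read_csv(fh, sep="\t", comment="#", dtype={"note": str})
    regions: list[EpitopeRegion] = []
    for row in frame.itertuples(index=False):
        note = "" if pd.isna(getattr(row, "note", "")) else str(row.note)
        span = int(row.end) - int(row.start) + 1
        if len(row.sequence) != span and not note:
            raise ValueError(
                f"{row.parent_id} epitope {row.epitope_index}: sequence length "
                f"{len(row.sequence)} != span {span} ({row.start}-{row.end}) and no "
                "note records the discrepancy"
            )
        regions.append(
            EpitopeRegion(
                parent_id=str(row.parent_id),
                start=int(row.start),
                end=int(row.end),
                sequence=str(row.sequence),
                kind=str(row.kind),
                epitope_index=int(row.epitope_index),
                note=note,
            )
        )
    return regions


def regions_to_frame(regions: Sequence[EpitopeRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "parent_id": r.parent_id,
                "epitope_index": r.epitope_index,
                "start": r.start,
                "end": r.end,
                "sequence": r.sequence,
                "kind": r.kind,
                "votes": r.votes,
                "note": r.note,
            }
            for r in regions
        ],
        columns=[
            "parent_id",
            "epitope_index",
            "start",
            "end",
            "sequence",
            "kind",
            "votes",
            "note",
        ],
    )


def write_regions(regions: Sequence[EpitopeRegion], path: str | Path) -> None:
    regions_to_frame(regions).to_csv(path, sep="\t", index=False)
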