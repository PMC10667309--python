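"""Presence calling and abundance/activity quantification from coverage tables.

An entity (viral contig, vOTU representative or MAG) is considered present
in a metagenome when more than 50% of its genome is covered by reads
(breadth of coverage). Abundance is the mean read depth normalized by the
library size; transcriptional activity is the analogous metatranscriptome
quantity, restricted to entities already DNA-present in the same sample.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "DetectionSummary",
    "call_presence",
    "normalized_abundance",
    "abundance_table",
    "transcript_activity",
    "summarize_sample",
]

#: Scale factor applied to depth/library ratios so abundances are readable
#: ("per million"); every downstream quantity of interest is a ratio and is
#: unaffected by this constant.
ABUNDANCE_SCALE = 1e6

_REQUIRED_COLS = ("entity_id", "sample_id", "breadth", "mean_depth", "library_size")


def _validate_records(records: pd.DataFrame) -> pd.DataFrame:
    df = pd.DataFrame(records)
    missing = [c for c in _REQUIRED_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"coverage table missing columns: {missing}")
    if df.duplicated(["entity_id", "sample_id"]).any():
        dups = df[df.duplicated(["entity_id", "sample_id"])]["entity_id"].tolist()
        raise ValueError(f"duplicate (entity, sample) coverage records: {dups[:5]}")
    if ((df["breadth"] < 0) | (df["breadth"] > 1)).any():
        raise ValueError("breadth outside [0, 1]")
    if (df["mean_depth"] < 0).any():
        raise ValueError("negative mean_depth")
    if (df["library_size"] <= 0).any():
        raise ValueError("library_size must be positive")
    return df


def call_presence(records: pd.DataFrame, breadth_cut: float = 0.5) -> pd.DataFrame:
    """Presence calls from breadth of coverage.

    An entity is present iff ``breadth > breadth_cut`` — strictly more than
    half the genome covered under the default. Returns the validated table
    with a boolean ``present`` column added.
    """
    df = _validate_records(records)
    df = df.copy()
    df["present"] = df["breadth"] > breadth_cut
    return df


def normalized_abundance(
    mean_depth: float, library_size: float, present: bool = True,
    scale: float = ABUNDANCE_SCALE,
) -> float:
    """Depth normalized by library size for one record; 0 when absent."""
    if library_size <= 0:
        raise ValueError("library_size must be positive")
    if not present:
        return 0.0
    return mean_depth / library_size * scale


def abundance_table(
    records: pd.DataFrame, breadth_cut: float = 0.5, scale: float = ABUNDANCE_SCALE
) -> pd.DataFrame:
    """Presence + normalized abundance for a whole coverage table.

    Entities failing the breadth cutoff get abundance 0 regardless of depth.
    """
    df = call_presence(records, breadth_cut=breadth_cut)
    df["abundance"] = np.where(
        df["present"], df["mean_depth"] / df["library_size"] * scale, 0.0
    )
    return df


def transcript_activity(
    records: pd.DataFrame,
    dna_presence: pd.DataFrame,
    scale: float = ABUNDANCE_SCALE,
) -> pd.DataFrame:
    """Transcriptional activity from metatranscriptome coverage.

    ``records`` must be restricted to entities that are DNA-present in the
    same sample (the read mapping upstream is done against positively
    detected entities only); a record for a DNA-absent entity is an error.
    An entity is active iff its transcript depth is > 0; the activity value
    is depth normalized by the metatranscriptome library size. The breadth
    rule is applied to DNA only, not to RNA coverage.
    """
    df = _validate_records(records)
    present_keys = set(
        map(
            tuple,
            dna_presence.loc[dna_presence["present"], ["entity_id", "sample_id"]]
            .itertuples(index=False),
        )
    )
    bad = [
        (e, s)
        for e, s in df[["entity_id", "sample_id"]].itertuples(index=False)
        if (e, s) not in present_keys
    ]
    if bad:
        raise ValueError(
            f"metatranscriptome records for entities not DNA-present: {bad[:5]}"
        )
    df = df.copy()
    df["active"] = df["mean_depth"] > 0
    df["activity"] = df["mean_depth"] / df["library_size"] * scale
    return df


@dataclass
class DetectionSummary:
    """Per-sample summary of host-associated vOTU detection.

    Fractions are NaN (explicit NA) when their denominator is empty, never
    silently 0.
    """

    sample_id: str
    n_votus_detected: int
    n_host_associated: int
    relative_richness: float
    relative_abundance: float
    active_fraction_host_associated: float
    transcript_fraction_host_associated: float
    relative_richness_multi: float = math.nan
    relative_richness_one: float = math.nan
    relative_abundance_multi: float = math.nan
    relative_abundance_one: float = math.nan

    def as_dict(self) -> dict:
        return asdict(self)


def _frac(num: float, den: float) -> float:
    return num / den if den else math.nan


def summarize_sample(
    presence: pd.DataFrame,
    abundance: pd.DataFrame,
    activity: pd.DataFrame | None,
    host_associated_ids: Iterable[str],
    host_range_class: Mapping[str, str] | None = None,
) -> DetectionSummary:
    """Summary fractions for one sample's vOTU tables.

    Computes the richness and abundance of host-associated vOTUs relative
    to all detected vOTUs, the fraction of transcriptionally active vOTUs
    that are host-associated, and the fraction of transcripts mapping to
    host-associated vOTUs. When ``host_range_class`` (vOTU id ->
    ``multiple_hosts`` | ``one_host``) is supplied, the multi-host vs
    one-host richness/abundance splits are also filled in.

    ``host_associated_ids`` must be a subset of the detected entities;
    violations are reported in the raised error rather than dropped.
    """
    sample_ids = set(presence["sample_id"].unique())
    if len(sample_ids) != 1:
        raise ValueError(f"expected a single sample, got {sorted(sample_ids)}")
    (sample_id,) = sample_ids

    detected = set(presence.loc[presence["present"], "entity_id"])
    host_assoc = set(host_associated_ids)
    stray = host_assoc - detected
    if stray:
        raise ValueError(
            f"host-associated ids not detected in sample {sample_id}: "
            f"{sorted(stray)[:10]}"
        )
    if not detected:
        nan = math.nan
        return DetectionSummary(sample_id, 0, 0, nan, nan, nan, nan)

    ab = abundance.set_index("entity_id")["abundance"]
    total_ab = float(ab.reindex(sorted(detected)).fillna(0.0).sum())

    def subset_ab(ids: set[str]) -> float:
        if not ids:
            return 0.0
        return float(ab.reindex(sorted(ids)).fillna(0.0).sum())

    if activity is not None and len(activity):
        active = set(activity.loc[activity["active"], "entity_id"])
        act = activity.set_index("entity_id")["activity"]
        total_act = float(act.reindex(sorted(active)).fillna(0.0).sum())
        active_frac = _frac(len(active & host_assoc), len(active))
        transcript_frac = (
            _frac(float(act.reindex(sorted(active & host_assoc)).fillna(0.0).sum()), total_act)
            if total_act
            else math.nan
        )
    else:
        active_frac = math.nan
        transcript_frac = math.nan

    summary = DetectionSummary(
        sample_id=sample_id,
        n_votus_detected=len(detected),
        n_host_associated=len(host_assoc),
        relative_richness=_frac(len(host_assoc), len(detected)),
        relative_abundance=_frac(subset_ab(host_assoc), total_ab) if total_ab else math.nan,
        active_fraction_host_associated=active_frac,
        transcript_fraction_host_associated=transcript_frac,
    )
    if host_range_class is not None:
        multi = {v for v in host_assoc if host_range_class.get(v) == "multiple_hosts"}
        one = {v for v in host_assoc if host_range_class.get(v) == "one_host"}
        summary.relative_richness_multi = _frac(len(multi), len(detected))
        summary.relative_richness_one = _frac(len(one), len(detected))
        if total_ab:
            summary.relative_abundance_multi = _frac(subset_ab(multi), total_ab)
            summary.relative_abundance_one = _frac(subset_ab(one), total_ab)
    return summary
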