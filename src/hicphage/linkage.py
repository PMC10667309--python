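r"""Hi-C phage-host linkage: VPH estimation and two-round link filtering.

This is the core of the pipeline. Hi-C proximity ligation produces chimeric
read pairs joining DNA molecules that were physically co-located in one
cell; an inter-entity read pair joining a viral contig to a MAG is evidence
the phage was inside that host at sampling time. From per-replicate link
tables, candidate (phage, MAG) pairs are scored with two quantities:

* the average viral copies per host cell,

      VPH = (V / H) * (L / sum L(v)),

  where ``V`` and ``H`` are the phage's and host's normalized abundances,
  ``L`` the Hi-C link count of the pair, and ``sum L(v)`` the phage's links
  to all possible hosts; and

* the phage-host connectivity ratio,

      R' = (D_VH / D_H) * (H * sum L(v)) / (V * L),

  where ``D_VH = L / (len_v * len_h)`` and ``D_H = intra / len_h**2`` are
  Hi-C links per kb^2 of the pair and of the MAG to itself. The two
  satisfy the identity ``R' * VPH = D_VH / D_H``.

Candidates then pass two rounds of filtering: round one requires at least
2 links, R' >= 0.1 and intra-MAG connectivity of at least 10 links; round
two applies an ROC-style threshold scan (maximize the number of phages
keeping at least one host while removing as many links as possible), drops
links whose replicate-averaged count is below 80% of the strongest link of
the same viral contig, and flags promiscuous phages linked to an excessive
fraction of all MAGs. Survivors are collapsed to vOTU x dereplicated-host
infection pairs with replicate support.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .catalog import Cluster, cluster_membership

__all__ = [
    "ReadPairRecord",
    "LinkTable",
    "PhageHostCandidate",
    "InfectionPair",
    "aggregate_read_pairs",
    "build_candidates",
    "compute_vph",
    "compute_r_prime",
    "round1_filter",
    "roc_threshold",
    "relative_count_filter",
    "promiscuity_adjust",
    "collapse_to_pairs",
    "vph_per_host",
]


# ---------------------------------------------------------------------------
# Data containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ReadPairRecord:
    """One Hi-C read pair after alignment, before quality filtering."""

    read_id: str
    contig_a: str
    contig_b: str
    mapq_a: int
    mapq_b: int
    is_duplicate: bool = False
    is_primary_a: bool = True
    is_primary_b: bool = True


@dataclass
class LinkTable:
    """Symmetric entity-level Hi-C link counts for one replicate.

    Entities are viral contigs and MAGs. ``entries`` maps canonically
    ordered (entity_a, entity_b) pairs to non-negative integer counts;
    ``intra`` holds each MAG's internal connectivity (links between
    distinct contigs of the same MAG). ``lengths`` are entity lengths
    in kb.
    """

    replicate_id: str
    condition: str
    entries: dict[tuple[str, str], int] = field(default_factory=dict)
    lengths: dict[str, float] = field(default_factory=dict)
    intra: dict[str, int] = field(default_factory=dict)

    @staticmethod
    def _key(a: str, b: str) -> tuple[str, str]:
        return (a, b) if a <= b else (b, a)

    def add(self, a: str, b: str, n: int = 1) -> None:
        if n < 0:
            raise ValueError("link counts must be non-negative")
        if a == b:
            self.intra[a] = self.intra.get(a, 0) + n
        else:
            k = self._key(a, b)
            self.entries[k] = self.entries.get(k, 0) + n

    def get(self, a: str, b: str) -> int:
        return self.entries.get(self._key(a, b), 0)

    def links_of(self, entity: str) -> dict[str, int]:
        """All inter-entity link counts involving ``entity``."""
        out: dict[str, int] = {}
        for (a, b), n in self.entries.items():
            if a == entity:
                out[b] = n
            elif b == entity:
                out[a] = n
        return out

    def to_frame(self) -> pd.DataFrame:
        rows = [(a, b, n) for (a, b), n in sorted(self.entries.items())]
        rows += [(m, m, n) for m, n in sorted(self.intra.items())]
        return pd.DataFrame(rows, columns=["entity_a", "entity_b", "count"])

    @classmethod
    def from_frame(
        cls,
        frame: pd.DataFrame,
        replicate_id: str,
        condition: str,
        lengths: Mapping[str, float] | None = None,
    ) -> "LinkTable":
        t = cls(replicate_id=replicate_id, condition=condition,
                lengths=dict(lengths or {}))
        for r in frame.itertuples(index=False):
            t.add(r.entity_a, r.entity_b, int(r.count))
        return t


@dataclass
class PhageHostCandidate:
    """One (viral contig, MAG, replicate) link with every derived quantity."""

    phage_id: str
    mag_id: str
    replicate_id: str
    condition: str
    L: int
    sum_Lv: int
    V: float
    H: float
    intra: int
    len_phage_kb: float
    len_mag_kb: float
    D_VH: float = 0.0
    D_H: float = 0.0
    vph: float = 0.0
    r_prime: float = 0.0
    flags: dict = field(default_factory=dict)
    reject_reason: str | None = None


@dataclass
class InfectionPair:
    """A collapsed (vOTU, dereplicated host population) infection pair."""

    votu_id: str
    population_id: str
    condition: str
    replicate_support: frozenset
    host_range_class: str  # "multiple_hosts" | "one_host"


# ---------------------------------------------------------------------------
# Read-pair aggregation
# ---------------------------------------------------------------------------


def aggregate_read_pairs(
    records: Iterable[ReadPairRecord],
    contig_meta: pd.DataFrame,
    replicate_id: str = "r1",
    condition: str = "",
    min_mapq: int = 20,
    min_contig_kb: float = 1.0,
) -> LinkTable:
    """Aggregate aligned Hi-C read pairs into an entity-level link table.

    ``contig_meta`` needs columns ``contig_id``, ``length_kb``,
    ``entity_id`` (the MAG id for binned contigs, the contig's own id for
    viral contigs) and ``entity_type`` (``mag`` | ``phage``).

    Dropped read pairs: PCR duplicates, pairs with a non-primary alignment
    on either end, pairs with mapping quality below ``min_mapq`` on either
    end, pairs whose ends map to the same contig, and pairs touching a
    contig of at most ``min_contig_kb``. Pairs joining two distinct contigs
    of one MAG count toward that MAG's intra-MAG connectivity; pairs
    joining different entities count as inter-entity links.
    """
    meta = contig_meta.set_index("contig_id")
    table = LinkTable(replicate_id=replicate_id, condition=condition)
    ent_len = contig_meta.groupby("entity_id")["length_kb"].sum()
    table.lengths = {str(k): float(v) for k, v in ent_len.items()}
    for r in records:
        for c in (r.contig_a, r.contig_b):
            if c not in meta.index:
                raise KeyError(f"contig {c!r} absent from metadata")
        if r.is_duplicate or not (r.is_primary_a and r.is_primary_b):
            continue
        if r.mapq_a < min_mapq or r.mapq_b < min_mapq:
            continue
        if r.contig_a == r.contig_b:
            continue
        la = float(meta.at[r.contig_a, "length_kb"])
        lb = float(meta.at[r.contig_b, "length_kb"])
        if la <= min_contig_kb or lb <= min_contig_kb:
            continue
        ea = str(meta.at[r.contig_a, "entity_id"])
        eb = str(meta.at[r.contig_b, "entity_id"])
        if ea == eb:
            if str(meta.at[r.contig_a, "entity_type"]) == "mag":
                table.intra[ea] = table.intra.get(ea, 0) + 1
            # distinct contigs of one viral entity are not counted
        else:
            table.add(ea, eb, 1)
    return table


# ---------------------------------------------------------------------------
# VPH and connectivity ratio
# ---------------------------------------------------------------------------


def compute_vph(c: PhageHostCandidate) -> float:
    """Average viral copies per host cell for one candidate.

    ``vph = (V / H) * (L / sum_Lv)``. Requires a positive host abundance
    and a positive phage link total; a candidate violating either is
    undefined and must be rejected by the caller.
    """
    if c.H <= 0:
        raise ValueError(f"H = {c.H} for ({c.phage_id}, {c.mag_id}): VPH undefined")
    if c.sum_Lv <= 0:
        raise ValueError(
            f"sum L(v) = {c.sum_Lv} for ({c.phage_id}, {c.mag_id}): VPH undefined"
        )
    return (c.V / c.H) * (c.L / c.sum_Lv)


def compute_r_prime(c: PhageHostCandidate) -> float:
    """Phage-host connectivity ratio R' for one candidate.

    ``D_VH = L / (len_v * len_h)`` and ``D_H = intra / len_h**2`` are link
    densities per kb^2; ``R' = (D_VH / D_H) * (H * sum_Lv) / (V * L)``.
    Satisfies ``R' * VPH = D_VH / D_H`` exactly. A candidate with zero
    intra-MAG links has an undefined density ratio and is rejected (it
    would fail the intra-connectivity filter regardless).
    """
    if c.intra <= 0:
        raise ValueError(
            f"intra-MAG links = {c.intra} for {c.mag_id}: D_H undefined"
        )
    if c.V <= 0 or c.L <= 0:
        raise ValueError(
            f"V = {c.V}, L = {c.L} for ({c.phage_id}, {c.mag_id}): R' undefined"
        )
    d_vh = c.L / (c.len_phage_kb * c.len_mag_kb)
    d_h = c.intra / (c.len_mag_kb**2)
    return (d_vh / d_h) * (c.H * c.sum_Lv) / (c.V * c.L)


def build_candidates(
    table: LinkTable,
    abundance: Mapping[str, float],
    entity_types: Mapping[str, str],
) -> tuple[list[PhageHostCandidate], list[PhageHostCandidate]]:
    """Build scored candidates from one replicate's link table.

    Every phage-MAG entry with a positive count becomes a candidate.
    ``sum_Lv`` is the phage's total links to *all* MAGs in the table,
    evaluated before any filtering. ``abundance`` maps entity id to its
    normalized abundance in the matching metagenome sample (0 or missing
    means not detected). Candidates whose VPH or R' is undefined (host or
    phage abundance 0, no intra-MAG links) are returned separately with a
    ``reject_reason`` so the audit trail is complete.
    """
    sum_links: dict[str, int] = defaultdict(int)
    pair_rows: list[tuple[str, str, int]] = []
    for (a, b), n in sorted(table.entries.items()):
        ta, tb = entity_types.get(a), entity_types.get(b)
        if ta == "phage" and tb == "mag":
            phage, mag = a, b
        elif ta == "mag" and tb == "phage":
            phage, mag = b, a
        else:
            continue  # MAG-MAG and phage-phage links play no role here
        sum_links[phage] += n
        pair_rows.append((phage, mag, n))

    kept: list[PhageHostCandidate] = []
    rejected: list[PhageHostCandidate] = []
    for phage, mag, n in pair_rows:
        c = PhageHostCandidate(
            phage_id=phage,
            mag_id=mag,
            replicate_id=table.replicate_id,
            condition=table.condition,
            L=n,
            sum_Lv=sum_links[phage],
            V=float(abundance.get(phage, 0.0)),
            H=float(abundance.get(mag, 0.0)),
            intra=int(table.intra.get(mag, 0)),
            len_phage_kb=float(table.lengths[phage]),
            len_mag_kb=float(table.lengths[mag]),
        )
        c.D_VH = c.L / (c.len_phage_kb * c.len_mag_kb)
        c.D_H = c.intra / (c.len_mag_kb**2)
        try:
            c.vph = compute_vph(c)
            if c.vph <= 0:
                raise ValueError("VPH = 0 (phage not detected in metagenome)")
            c.r_prime = compute_r_prime(c)
        except ValueError as err:
            c.reject_reason = str(err)
            rejected.append(c)
            continue
        kept.append(c)
    return kept, rejected


# ---------------------------------------------------------------------------
# Round-1 and round-2 filters
# ---------------------------------------------------------------------------


def round1_filter(
    cands: Sequence[PhageHostCandidate],
    min_links: int = 2,
    min_ratio: float = 0.1,
    min_intra: int = 10,
) -> list[PhageHostCandidate]:
    """First-round filter: link support, connectivity ratio, intra-MAG links.

    Keeps candidates with ``L >= min_links`` and ``r_prime >= min_ratio``
    and ``intra >= min_intra`` (all thresholds inclusive; the ratio
    comparison allows 1e-9 relative slack so a candidate sitting exactly on
    the threshold is not lost to floating-point rounding). Flags are set on
    every candidate; counts are never mutated.
    """
    import math as _math

    out = []
    for c in cands:
        c.flags["min_links"] = c.L >= min_links
        c.flags["ratio"] = c.r_prime >= min_ratio or _math.isclose(
            c.r_prime, min_ratio, rel_tol=1e-9
        )
        c.flags["intra"] = c.intra >= min_intra
        if c.flags["min_links"] and c.flags["ratio"] and c.flags["intra"]:
            out.append(c)
    return out


def roc_threshold(
    cands: Sequence[PhageHostCandidate],
    score: Callable[[PhageHostCandidate], float] | str = "r_prime",
) -> tuple[float, list[PhageHostCandidate]]:
    """Second-round ROC-style threshold on a candidate score.

    Scans every unique score value ``t`` and keeps candidates with
    ``score >= t``. The objective combines the two stated goals
    Youden-style: ``f(t)``, the fraction of phages retaining at least one
    host, plus ``g(t)``, the fraction of links removed; the ``t``
    maximizing ``f + g`` wins, ties going to the smallest ``t`` (the least
    destructive threshold).
    """
    if not cands:
        raise ValueError("roc_threshold requires a non-empty candidate list")
    get = (lambda c: getattr(c, score)) if isinstance(score, str) else score
    scores = np.array([get(c) for c in cands], dtype=float)
    phages = [c.phage_id for c in cands]
    n_links = len(cands)
    n_phages = len(set(phages))
    best_t, best_obj = None, -np.inf
    for t in sorted(set(scores.tolist())):
        keep = scores >= t
        f = len({p for p, k in zip(phages, keep) if k}) / n_phages
        g = (n_links - int(keep.sum())) / n_links
        if f + g > best_obj:  # strict: ties resolved to the smallest t
            best_obj, best_t = f + g, t
    survivors = []
    for c in cands:
        ok = get(c) >= best_t
        c.flags["roc"] = ok
        if ok:
            survivors.append(c)
    return float(best_t), survivors


def relative_count_filter(
    cands: Sequence[PhageHostCandidate], frac: float = 0.8
) -> list[PhageHostCandidate]:
    """Drop weak links of each viral contig relative to its strongest link.

    Within each (condition, phage) group, a (phage, MAG) link is dropped
    when its link count — averaged over the replicates in which the pair
    appears — is strictly less than ``frac`` times the highest averaged
    count among that phage's links. Within a single replicate the average
    degrades to the raw count.
    """
    sums: dict[tuple, float] = defaultdict(float)
    counts: dict[tuple, int] = defaultdict(int)
    for c in cands:
        k = (c.condition, c.phage_id, c.mag_id)
        sums[k] += c.L
        counts[k] += 1
    mean_l = {k: sums[k] / counts[k] for k in sums}
    max_by_phage: dict[tuple, float] = defaultdict(float)
    for (cond, phage, _mag), m in mean_l.items():
        max_by_phage[(cond, phage)] = max(max_by_phage[(cond, phage)], m)
    out = []
    for c in cands:
        m = mean_l[(c.condition, c.phage_id, c.mag_id)]
        ok = not (m < frac * max_by_phage[(c.condition, c.phage_id)])
        c.flags["relative80"] = ok
        if ok:
            out.append(c)
    return out


def promiscuity_adjust(
    cands: Sequence[PhageHostCandidate],
    n_mags_total: int | Mapping[tuple[str, str], int],
    max_host_fraction: float = 0.2,
    remove: bool = True,
) -> tuple[list[PhageHostCandidate], pd.DataFrame]:
    """Flag (and by default remove) promiscuously linked phages.

    A phage linked to more than ``max_host_fraction`` of all MAGs within a
    replicate is likely rich in false-positive interactions (e.g. a
    repeat-laden sequence). Such phages are always reported; under the
    default policy their candidates are removed, but the report lets a
    user override the decision. ``n_mags_total`` is the total MAG count,
    either global or per (condition, replicate).
    """
    hosts: dict[tuple, set] = defaultdict(set)
    for c in cands:
        hosts[(c.condition, c.replicate_id, c.phage_id)].add(c.mag_id)
    flagged: set[tuple] = set()
    rows = []
    for (cond, rep, phage), mags in sorted(hosts.items()):
        total = (
            n_mags_total
            if isinstance(n_mags_total, int)
            else n_mags_total[(cond, rep)]
        )
        fraction = len(mags) / total
        if fraction > max_host_fraction:
            flagged.add((cond, rep, phage))
            rows.append((cond, rep, phage, len(mags), total, fraction))
    report = pd.DataFrame(
        rows,
        columns=["condition", "replicate_id", "phage_id", "n_hosts",
                 "n_mags_total", "host_fraction"],
    )
    out = []
    for c in cands:
        hit = (c.condition, c.replicate_id, c.phage_id) in flagged
        c.flags["promiscuity"] = not hit
        if not hit or not remove:
            out.append(c)
    return out, report


# ---------------------------------------------------------------------------
# Collapse to infection pairs
# ---------------------------------------------------------------------------


def collapse_to_pairs(
    cands: Sequence[PhageHostCandidate],
    votu_clusters: Sequence[Cluster],
    mag_derep: Sequence[Cluster],
) -> list[InfectionPair]:
    """Collapse surviving candidates to vOTU x host-population pairs.

    Viral contigs in the same vOTU and MAGs in the same >=99%-identity
    dereplicated population are merged; the pair's replicate support is
    the set of replicates contributing any member-level candidate. A vOTU
    linked to two or more distinct populations within a condition is
    classed ``multiple_hosts``, otherwise ``one_host``.
    """
    votu_of = cluster_membership(votu_clusters)
    pop_of = cluster_membership(mag_derep)
    support: dict[tuple, set] = defaultdict(set)
    for c in cands:
        if c.phage_id not in votu_of:
            raise KeyError(f"phage {c.phage_id!r} not assigned to any vOTU")
        if c.mag_id not in pop_of:
            raise KeyError(f"MAG {c.mag_id!r} not assigned to any population")
        support[(votu_of[c.phage_id], pop_of[c.mag_id], c.condition)].add(
            c.replicate_id
        )
    hosts_per_votu: dict[tuple, set] = defaultdict(set)
    for votu, pop, cond in support:
        hosts_per_votu[(votu, cond)].add(pop)
    pairs = [
        InfectionPair(
            votu_id=votu,
            population_id=pop,
            condition=cond,
            replicate_support=frozenset(reps),
            host_range_class=(
                "multiple_hosts"
                if len(hosts_per_votu[(votu, cond)]) >= 2
                else "one_host"
            ),
        )
        for (votu, pop, cond), reps in sorted(support.items())
    ]
    return pairs


def vph_per_host(
    cands: Sequence[PhageHostCandidate],
    mag_derep: Sequence[Cluster],
) -> pd.DataFrame:
    """Total VPH per host population, condition and replicate.

    For each dereplicated host population the VPH contributions of all its
    surviving phage links are summed within a replicate. Populations with
    no surviving links are absent from the table (not zero), matching how
    a host only yields a data point when it is phage-linked.
    """
    pop_of = cluster_membership(mag_derep)
    totals: dict[tuple, float] = defaultdict(float)
    for c in cands:
        totals[(pop_of[c.mag_id], c.condition, c.replicate_id)] += c.vph
    rows = [
        (pop, cond, rep, v) for (pop, cond, rep), v in sorted(totals.items())
    ]
    return pd.DataFrame(
        rows, columns=["population_id", "condition", "replicate_id", "total_vph"]
    )


def candidates_to_frame(cands: Sequence[PhageHostCandidate]) -> pd.DataFrame:
    """Flatten candidates (with filter flags) into a tidy table."""
    rows = []
    for c in cands:
        row = {
            "phage_id": c.phage_id,
            "mag_id": c.mag_id,
            "replicate_id": c.replicate_id,
            "condition": c.condition,
            "L": c.L,
            "sum_Lv": c.sum_Lv,
            "V": c.V,
            "H": c.H,
            "intra": c.intra,
            "len_phage_kb": c.len_phage_kb,
            "len_mag_kb": c.len_mag_kb,
            "D_VH": c.D_VH,
            "D_H": c.D_H,
            "vph": c.vph,
            "r_prime": c.r_prime,
            "reject_reason": c.reject_reason or "",
        }
        for k, v in c.flags.items():
            row[f"flag_{k}"] = v
        rows.append(row)
    return pd.DataFrame(rows)
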