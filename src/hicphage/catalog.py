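"""Viral-contig catalogue construction.

Covers the sequence-catalogue side of the pipeline: the multi-tool voting
rule that decides which contigs are viral, greedy centroid clustering used
both for species-level vOTUs (95% ANI / 85% AF) and for host-MAG
dereplication (99% identity), CRISPR spacer-to-protospacer matching, and
the comparison of phage-host link sets obtained by independent methods.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ToolVote",
    "Cluster",
    "SpacerHit",
    "vote_viral_contigs",
    "greedy_centroid_cluster",
    "match_crispr_spacers",
    "crispr_link_set",
    "compare_link_sets",
]

#: CheckV quality tiers that let a single tool call carry the vote.
_RESCUE_QUALITIES = frozenset({"complete", "high", "medium"})
_VALID_QUALITIES = _RESCUE_QUALITIES | {"low", "not-determined"}


@dataclass(frozen=True)
class ToolVote:
    """Per-contig calls from the three viral detection tools plus CheckV.

    ``virsorter``, ``vibrant`` and ``deepvirfinder`` are the boolean calls
    after each tool's own score cutoffs were applied upstream; a
    sub-threshold call counts as "not viral" here.
    """

    contig_id: str
    virsorter: bool
    vibrant: bool
    deepvirfinder: bool
    checkv_quality: str = "not-determined"

    def __post_init__(self) -> None:
        if self.checkv_quality not in _VALID_QUALITIES:
            raise ValueError(
                f"unknown CheckV quality {self.checkv_quality!r} for "
                f"{self.contig_id}; expected one of {sorted(_VALID_QUALITIES)}"
            )

    @property
    def n_tool_calls(self) -> int:
        return int(self.virsorter) + int(self.vibrant) + int(self.deepvirfinder)


def vote_viral_contigs(votes: Iterable[ToolVote]) -> set[str]:
    """Classify contigs as viral by the two-of-three voting rule.

    A contig is viral iff at least two of the three tools call it viral,
    or exactly one tool calls it viral and CheckV rates the genome as
    complete or of high-to-medium quality.

    Raises
    ------
    ValueError
        If the same ``contig_id`` appears in more than one vote record.
    """
    seen: set[str] = set()
    viral: set[str] = set()
    for v in votes:
        if v.contig_id in seen:
            raise ValueError(f"duplicate vote record for contig {v.contig_id!r}")
        seen.add(v.contig_id)
        n = v.n_tool_calls
        if n >= 2 or (n == 1 and v.checkv_quality in _RESCUE_QUALITIES):
            viral.add(v.contig_id)
    return viral


@dataclass
class Cluster:
    """A greedy centroid cluster; the representative is the longest member."""

    representative_id: str
    member_ids: list[str] = field(default_factory=list)
    level: str = ""


def _sim_lookup(
    sims: Iterable[tuple] | Mapping,
) -> dict[tuple[str, str], tuple[float, float]]:
    """Build a symmetric (id_a, id_b) -> (ani, af) lookup.

    Accepts an iterable of ``(id_a, id_b, ani, af)`` tuples, objects with
    those attributes, or a pandas DataFrame with those columns. A missing
    pair is interpreted as below-cutoff similarity.
    """
    if hasattr(sims, "itertuples"):  # DataFrame
        rows = [
            (r.id_a, r.id_b, float(r.ani), float(r.af))
            for r in sims.itertuples(index=False)
        ]
    else:
        rows = []
        for s in sims:
            if isinstance(s, tuple):
                rows.append((s[0], s[1], float(s[2]), float(s[3])))
            else:
                rows.append((s.id_a, s.id_b, float(s.ani), float(s.af)))
    table: dict[tuple[str, str], tuple[float, float]] = {}
    for a, b, ani, af in rows:
        if not (0.0 <= ani <= 100.0 and 0.0 <= af <= 100.0):
            raise ValueError(f"ani/af outside [0, 100] for pair ({a}, {b})")
        table[(a, b)] = (ani, af)
        table[(b, a)] = (ani, af)
    return table


def greedy_centroid_cluster(
    items: Sequence[tuple[str, float]],
    sims: Iterable | Mapping,
    ani_cut: float = 95.0,
    af_cut: float = 85.0,
    level: str = "",
) -> list[Cluster]:
    """Greedy centroid clustering by pairwise ANI / aligned fraction.

    Items are scanned in descending length order (ties broken by id). Each
    item joins the first existing cluster whose *representative* it matches
    at ``ani >= ani_cut`` and ``af >= af_cut``; otherwise it founds a new
    cluster and becomes its representative. With (95, 85) this produces
    species-level vOTUs; with (99, 0) on a MAG identity table it produces
    dereplicated host populations.

    The aligned fraction is computed on the shorter sequence of the pair
    by the upstream aligner; this function only consumes the table.
    """
    for cid, length in items:
        if not length > 0:
            raise ValueError(f"non-positive length for {cid!r}: {length}")
    lut = _sim_lookup(sims)
    order = sorted(items, key=lambda t: (-t[1], t[0]))
    clusters: list[Cluster] = []
    for cid, _length in order:
        placed = False
        for cl in clusters:
            ani, af = lut.get((cid, cl.representative_id), (0.0, 0.0))
            if ani >= ani_cut and af >= af_cut:
                cl.member_ids.append(cid)
                placed = True
                break
        if not placed:
            clusters.append(Cluster(representative_id=cid, member_ids=[cid], level=level))
    return clusters


def cluster_membership(clusters: Iterable[Cluster]) -> dict[str, str]:
    """Map every member id to its cluster representative id."""
    out: dict[str, str] = {}
    for cl in clusters:
        for m in cl.member_ids:
            if m in out:
                raise ValueError(f"id {m!r} appears in more than one cluster")
            out[m] = cl.representative_id
    return out


# ---------------------------------------------------------------------------
# CRISPR spacer matching
# ---------------------------------------------------------------------------

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


@dataclass(frozen=True)
class SpacerHit:
    spacer_id: str
    mag_id: str
    contig_id: str
    mismatches: int
    strand: str  # "+" or "-"
    offset: int


def _seq_records(viral_seqs) -> list[tuple[str, str]]:
    out = []
    for rec in viral_seqs:
        if isinstance(rec, tuple):
            out.append((rec[0], str(rec[1]).upper()))
        else:  # Bio.SeqRecord
            out.append((rec.id, str(rec.seq).upper()))
    return out


def _min_mismatch_offsets(spacer: str, contig: str) -> tuple[int, int] | None:
    """Best Hamming match of ``spacer`` against all offsets of ``contig``.

    Returns ``(mismatches, offset)`` for the best full-length ungapped
    placement, or None if the spacer is longer than the contig. Vectorized
    over offsets with a sliding byte-window comparison.
    """
    k, m = len(spacer), len(contig)
    if k > m:
        return None
    cbuf = np.frombuffer(contig.encode(), dtype=np.uint8)
    sbuf = np.frombuffer(spacer.encode(), dtype=np.uint8)
    windows = np.lib.stride_tricks.sliding_window_view(cbuf, k)
    mismatches = (windows != sbuf).sum(axis=1)
    off = int(np.argmin(mismatches))
    return int(mismatches[off]), off


def match_crispr_spacers(
    spacers: Iterable[tuple[str, str, str]],
    viral_seqs,
    min_identity: float = 95.0,
    max_mismatch: int = 1,
    min_spacer_len: int = 18,
) -> list[SpacerHit]:
    """Match CRISPR spacers against viral contigs to predict phage-host links.

    A hit is a full-length, ungapped spacer alignment on either strand of a
    viral contig with at most ``max_mismatch`` mismatches and percent
    identity of at least ``min_identity``. Per spacer only the single best
    target is reported (fewest mismatches; ties broken toward the longest
    contig, then lexicographically smallest contig id).

    Parameters
    ----------
    spacers
        Iterable of ``(spacer_id, mag_id, sequence)``; sequences over ACGT.
    viral_seqs
        Bio.SeqRecord iterable or ``(contig_id, sequence)`` tuples.
    """
    contigs = _seq_records(viral_seqs)
    if not contigs:
        raise ValueError("viral sequence set is empty")
    hits: list[SpacerHit] = []
    for spacer_id, mag_id, seq in spacers:
        seq = str(seq).upper()
        if len(seq) < min_spacer_len:
            raise ValueError(
                f"spacer {spacer_id!r} is {len(seq)} nt, below the "
                f"{min_spacer_len} nt minimum"
            )
        if set(seq) - set("ACGT"):
            raise ValueError(f"spacer {spacer_id!r} has non-ACGT characters")
        rc = seq.translate(_COMPLEMENT)[::-1]
        best: tuple | None = None  # (mm, -len(contig), contig_id, strand, offset)
        for contig_id, cseq in contigs:
            for strand, query in (("+", seq), ("-", rc)):
                res = _min_mismatch_offsets(query, cseq)
                if res is None:
                    continue
                mm, off = res
                identity = 100.0 * (len(seq) - mm) / len(seq)
                if mm <= max_mismatch and identity >= min_identity:
                    key = (mm, -len(cseq), contig_id, strand, off)
                    if best is None or key < best:
                        best = key
        if best is not None:
            mm, _neglen, contig_id, strand, off = best
            hits.append(SpacerHit(spacer_id, mag_id, contig_id, mm, strand, off))
    return hits


def crispr_link_set(hits: Iterable[SpacerHit]) -> set[tuple[str, str]]:
    """Deduplicate spacer hits to unique (mag_id, contig_id) links."""
    return {(h.mag_id, h.contig_id) for h in hits}


def compare_link_sets(
    hic_pairs: set,
    crispr_pairs: set,
    level_a: str | None = None,
    level_b: str | None = None,
) -> dict:
    """Overlap report between two phage-host link sets on a common key level.

    Both sets must be keyed on the same level (e.g. (contig, MAG) or
    (vOTU, population)); declare the levels to have this checked. Returns
    ``n_a``, ``n_b``, ``overlap`` and Jaccard index (NaN when both empty).
    """
    if level_a is not None and level_b is not None and level_a != level_b:
        raise ValueError(
            f"link sets keyed at different levels: {level_a!r} vs {level_b!r}"
        )
    a, b = set(hic_pairs), set(crispr_pairs)
    inter = a & b
    union = a | b
    return {
        "n_a": len(a),
        "n_b": len(b),
        "overlap": len(inter),
        "jaccard": (len(inter) / len(union)) if union else math.nan,
    }
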