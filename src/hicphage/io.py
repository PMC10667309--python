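"""Readers and writers for the TSV dataset-directory layout.

The on-disk contract (shared by the simulator and real-data imports):

* ``entities.tsv`` — entity_id, entity_type (mag|phage), length_kb
* ``links.<condition>.<replicate>.tsv`` — entity_a, entity_b, count;
  rows with entity_a == entity_b carry a MAG's intra-MAG connectivity
* ``coverage.metagenome.<sample>.tsv`` /
  ``coverage.metatranscriptome.<sample>.tsv`` — entity_id, sample_id,
  breadth, mean_depth, library_size; sample ids are <condition>_<replicate>
* ``transcripts.tsv`` — argS-proxy relative abundances, samples x proxies
* ``votu_sims.tsv`` / ``mag_sims.tsv`` — id_a, id_b, ani, af (sparse;
  missing pair means below cutoff)
* ``votes.tsv`` (optional) — contig_id, virsorter, vibrant,
  deepvirfinder, checkv_quality
* ``truth.json`` (optional) — simulator ground truth
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .linkage import LinkTable
from .synthetic import GroundTruth, Infection

__all__ = ["Dataset", "load_dataset", "write_tsv"]

TSV_KW = dict(sep="\t", index=False, float_format="%.10g")


def write_tsv(df: pd.DataFrame, path: Path | str) -> None:
    """Write a table deterministically (fixed float format, no index)."""
    df.to_csv(path, **TSV_KW)


class Dataset:
    """In-memory view of a dataset directory."""

    def __init__(self, path: Path):
        self.path = Path(path)
        self.entities: pd.DataFrame = None
        self.link_tables: dict[tuple[str, str], LinkTable] = {}
        self.metagenome_coverage: dict[str, pd.DataFrame] = {}
        self.metatranscriptome_coverage: dict[str, pd.DataFrame] = {}
        self.transcripts: pd.DataFrame = None
        self.votu_sims: pd.DataFrame = None
        self.mag_sims: pd.DataFrame = None
        self.votes: pd.DataFrame | None = None
        self.truth: GroundTruth | None = None
        self.meta: dict = {}

    @property
    def conditions(self) -> list[str]:
        present = {cond for cond, _ in self.link_tables}
        declared = [c for c in self.meta.get("conditions", []) if c in present]
        return declared or sorted(present)

    def replicates(self, condition: str) -> list[str]:
        return sorted(rep for cond, rep in self.link_tables if cond == condition)

    def lengths(self) -> dict[str, float]:
        return dict(zip(self.entities["entity_id"], self.entities["length_kb"]))

    def entity_types(self) -> dict[str, str]:
        return dict(zip(self.entities["entity_id"], self.entities["entity_type"]))


def _require(path: Path, stage: str) -> Path:
    if not path.exists():
        raise FileNotFoundError(f"[{stage}] required input missing: {path}")
    return path


def load_dataset(path: str | Path) -> Dataset:
    """Load a dataset directory into memory, validating required tables."""
    path = Path(path)
    ds = Dataset(path)
    ds.entities = pd.read_csv(_require(path / "entities.tsv", "load"), sep="\t")
    lengths = ds.lengths()

    link_files = sorted(path.glob("links.*.tsv"))
    if not link_files:
        raise FileNotFoundError(f"[load] no links.<condition>.<replicate>.tsv in {path}")
    for f in link_files:
        _, cond, rep, _ = f.name.split(".")
        frame = pd.read_csv(f, sep="\t")
        ds.link_tables[(cond, rep)] = LinkTable.from_frame(
            frame, replicate_id=rep, condition=cond, lengths=lengths
        )

    for f in sorted(path.glob("coverage.metagenome.*.tsv")):
        sid = f.name[len("coverage.metagenome."):-len(".tsv")]
        ds.metagenome_coverage[sid] = pd.read_csv(f, sep="\t")
    for f in sorted(path.glob("coverage.metatranscriptome.*.tsv")):
        sid = f.name[len("coverage.metatranscriptome."):-len(".tsv")]
        ds.metatranscriptome_coverage[sid] = pd.read_csv(f, sep="\t")
    if not ds.metagenome_coverage:
        raise FileNotFoundError(f"[load] no coverage.metagenome.*.tsv in {path}")

    tfile = path / "transcripts.tsv"
    if tfile.exists():
        ds.transcripts = pd.read_csv(tfile, sep="\t", index_col="sample_id")

    for attr, name in (("votu_sims", "votu_sims.tsv"), ("mag_sims", "mag_sims.tsv")):
        f = path / name
        setattr(
            ds,
            attr,
            pd.read_csv(f, sep="\t")
            if f.exists()
            else pd.DataFrame(columns=["id_a", "id_b", "ani", "af"]),
        )

    vfile = path / "votes.tsv"
    if vfile.exists():
        ds.votes = pd.read_csv(vfile, sep="\t")

    cfile = path / "config.json"
    if cfile.exists():
        ds.meta = json.loads(cfile.read_text())

    tr = path / "truth.json"
    if tr.exists():
        payload = json.loads(tr.read_text())
        ds.truth = GroundTruth(
            hosts=pd.DataFrame(payload["hosts"]),
            phages=pd.DataFrame(payload["phages"]),
            infections=[Infection(**i) for i in payload["infections"]],
        )
    return ds
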