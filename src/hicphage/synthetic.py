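"""Synthetic soil-community generator with recorded ground truth.

Emulates the data a Hi-C phage-host study produces — host MAGs with
log-normal abundances, phages with known (generalist or specialist) host
ranges and per-infection true viral copies per host (VPH), per-replicate
Hi-C link tables, metagenome and metatranscriptome coverage tables and an
argS-proxy transcript matrix — across a replicated two-condition design
(a wet baseline and a post-drying treatment by default). Every generative
choice is recorded in a :class:`GroundTruth` object so downstream filtering
can be scored for precision, recall and VPH recovery.

Generative model (per condition x replicate):

* intra-MAG links       ~ Poisson(intra_link_rate * abundance * length_kb**2)
* phage-host pair links ~ Poisson(inter_link_efficiency * true_vph
                                  * host_abundance * phage_kb * host_kb)
* background noise      ~ Poisson(noise_link_rate) per unordered entity pair

The Hi-C noise process is not described by any published generative model;
the uniform background used here is an assumption and is documented as
such. Links are generated at the entity level (viral contig, MAG), the
level at which the VPH and connectivity-ratio estimators operate;
read-level aggregation is exercised on hand-written read tables instead.
Intra-phage self-links are not simulated — the intra-connectivity filter
applies to MAGs only.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .linkage import LinkTable

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "SimulatedDataset",
    "simulate_community",
    "truth_pair_set",
]


@dataclass
class SimulationConfig:
    """All tunable parameters of the synthetic community.

    The defaults describe a moderate-noise soil community of 100 host MAGs
    and 150 phage contigs sampled in 3 replicates under each of two
    conditions. Per-infection true VPH is drawn log-uniformly from
    ``vph_truth`` and coupled to log host abundance with a per-condition
    slope (negative pre-drying: lytic pressure suppresses abundant hosts;
    near zero post-drying), so the pre/post VPH contrast and the
    VPH-vs-abundance regression have a known generative signal.
    """

    n_hosts: int = 100
    n_phages: int = 150
    host_length_kb: tuple[float, float] = (2000.0, 6000.0)
    phage_length_kb: tuple[float, float] = (10.0, 80.0)
    host_abundance_mu: float = 0.0
    host_abundance_sigma: float = 1.0
    condition_abundance_sigma: float = 0.5
    p_generalist: float = 0.2
    host_range_size: tuple[int, int] = (2, 3)
    vph_truth: tuple[float, float] = (0.2, 2.0)
    vph_loghost_slopes: tuple[float, ...] = (-0.41, 0.089)
    vph_log_noise_sd: float = 0.4
    condition_vph_multipliers: tuple[float, ...] = (1.0, 1.6)
    condition_activity_multipliers: tuple[float, ...] = (1.0, 0.3)
    p_lysogenic: float = 0.4
    lysogenic_activity_factor: float = 0.2
    p_transcript_dropout: float = 0.2
    # probability an infection is active in (both, first-only, second-only)
    condition_assignment: tuple[float, float, float] = (0.30, 0.35, 0.35)
    intra_link_rate: float = 2e-5
    inter_link_efficiency: float = 2e-4
    noise_link_rate: float = 0.05
    n_replicates: int = 3
    conditions: tuple[str, ...] = ("pre", "post")
    depth_per_abundance: float = 50.0
    depth_noise_cv: float = 0.1
    library_size: int = 4_000_000
    n_latent_factors: int = 3
    duplicate_proxy_mags: tuple[str, ...] = ()
    seed: int = 0

    def validate(self) -> None:
        if self.n_hosts < 1 or self.n_phages < 1 or self.n_replicates < 1:
            raise ValueError("counts must be >= 1")
        for p in (self.p_generalist, self.p_lysogenic, self.p_transcript_dropout):
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")
        if abs(sum(self.condition_assignment) - 1.0) > 1e-9:
            raise ValueError("condition_assignment must sum to 1")
        for lo, hi in (self.host_length_kb, self.phage_length_kb):
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid positive range ({lo}, {hi})")
        lo, hi = self.vph_truth
        # (0, 0) is allowed: it pins every true VPH to zero (no true links)
        if lo < 0 or hi < lo or (lo == 0 and hi > 0):
            raise ValueError(f"invalid vph_truth range ({lo}, {hi})")
        if self.host_range_size[0] < 1 or self.host_range_size[1] < self.host_range_size[0]:
            raise ValueError("invalid host_range_size range")
        if len(self.conditions) != len(set(self.conditions)):
            raise ValueError("condition labels must be unique")
        for tup in (
            self.vph_loghost_slopes,
            self.condition_vph_multipliers,
            self.condition_activity_multipliers,
        ):
            if len(tup) != len(self.conditions):
                raise ValueError(
                    "per-condition parameter tuples must match the number of conditions"
                )
        # a pipeline where typical MAGs fail their own intra-connectivity is untestable
        expected_intra = (
            self.intra_link_rate
            * math.exp(self.host_abundance_mu)
            * self.host_length_kb[0] ** 2
        )
        if expected_intra < 1.0:
            raise ValueError(
                f"expected intra-MAG links at median abundance and minimum MAG "
                f"length is {expected_intra:.3g} < 1; increase intra_link_rate, "
                f"host length or abundance — the pipeline is untestable otherwise"
            )


@dataclass(frozen=True)
class Infection:
    phage_id: str
    mag_id: str
    condition: str
    true_vph: float


@dataclass
class GroundTruth:
    """The simulator's true hosts, phages and infections."""

    hosts: pd.DataFrame     # mag_id, length_kb, abundance.<condition>...
    phages: pd.DataFrame    # phage_id, length_kb, lifestyle, abundance.<condition>...
    infections: list[Infection]

    def host_range(self, phage_id: str) -> set[str]:
        return {i.mag_id for i in self.infections if i.phage_id == phage_id}

    def true_vph_map(self) -> dict[tuple[str, str, str], float]:
        return {
            (i.phage_id, i.mag_id, i.condition): i.true_vph for i in self.infections
        }


@dataclass
class SimulatedDataset:
    """Per-replicate link tables, coverage tables and transcript matrix."""

    entities: pd.DataFrame  # entity_id, entity_type, length_kb
    link_tables: dict[tuple[str, str], LinkTable]  # (condition, replicate) ->
    metagenome_coverage: dict[str, pd.DataFrame]   # sample_id ->
    metatranscriptome_coverage: dict[str, pd.DataFrame]
    transcripts: pd.DataFrame  # samples x argS proxies
    config: SimulationConfig

    def sample_id(self, condition: str, replicate: str) -> str:
        return f"{condition}_{replicate}"

    def to_directory(self, path: str | Path, truth: GroundTruth | None = None) -> None:
        """Write the dataset as a directory of TSV/JSON files.

        Layout: ``entities.tsv``, ``links.<condition>.<replicate>.tsv``
        (intra-MAG connectivity stored as entity_a == entity_b rows),
        ``coverage.metagenome.<sample>.tsv``,
        ``coverage.metatranscriptome.<sample>.tsv``, ``transcripts.tsv``,
        ``votu_sims.tsv`` / ``mag_sims.tsv`` (empty: every entity is its
        own cluster), ``config.json`` and optionally ``truth.json``.
        """
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        kw = dict(sep="\t", index=False, float_format="%.10g")
        self.entities.to_csv(path / "entities.tsv", **kw)
        for (cond, rep), table in sorted(self.link_tables.items()):
            table.to_frame().to_csv(path / f"links.{cond}.{rep}.tsv", **kw)
        for sid, df in sorted(self.metagenome_coverage.items()):
            df.to_csv(path / f"coverage.metagenome.{sid}.tsv", **kw)
        for sid, df in sorted(self.metatranscriptome_coverage.items()):
            df.to_csv(path / f"coverage.metatranscriptome.{sid}.tsv", **kw)
        self.transcripts.to_csv(path / "transcripts.tsv", sep="\t",
                                float_format="%.10g", index_label="sample_id")
        pd.DataFrame(columns=["id_a", "id_b", "ani", "af"]).to_csv(
            path / "votu_sims.tsv", **kw
        )
        pd.DataFrame(columns=["id_a", "id_b", "ani", "af"]).to_csv(
            path / "mag_sims.tsv", **kw
        )
        cfg = dataclasses.asdict(self.config)
        (path / "config.json").write_text(json.dumps(cfg, indent=1, sort_keys=True))
        if truth is not None:
            payload = {
                "hosts": truth.hosts.to_dict(orient="records"),
                "phages": truth.phages.to_dict(orient="records"),
                "infections": [dataclasses.asdict(i) for i in truth.infections],
            }
            (path / "truth.json").write_text(json.dumps(payload, indent=1, sort_keys=True))


def _draw_infections(cfg: SimulationConfig, rng, hosts, phages) -> list[Infection]:
    infections: list[Infection] = []
    mu = cfg.host_abundance_mu
    lo, hi = cfg.vph_truth
    mag_ids = hosts["mag_id"].to_numpy()
    for _, ph in phages.iterrows():
        if rng.random() < cfg.p_generalist:
            k = int(rng.integers(cfg.host_range_size[0], cfg.host_range_size[1] + 1))
            k = min(k, cfg.n_hosts)
        else:
            k = 1
        targets = rng.choice(mag_ids, size=k, replace=False)
        for mag_id in targets:
            u = rng.random()
            both, first_only, _ = cfg.condition_assignment
            if u < both:
                active = list(cfg.conditions)
            elif u < both + first_only:
                active = [cfg.conditions[0]]
            else:
                active = [cfg.conditions[min(1, len(cfg.conditions) - 1)]]
            for cond in active:
                ci = cfg.conditions.index(cond)
                if hi == 0:
                    vph = 0.0
                else:
                    h = float(hosts.loc[hosts["mag_id"] == mag_id,
                                        f"abundance.{cond}"].iloc[0])
                    log_vph = (
                        rng.uniform(math.log(lo), math.log(hi))
                        + cfg.vph_loghost_slopes[ci] * (math.log(h) - mu)
                        + rng.normal(0.0, cfg.vph_log_noise_sd)
                    )
                    vph = math.exp(log_vph) * cfg.condition_vph_multipliers[ci]
                infections.append(Infection(ph["phage_id"], str(mag_id), cond, vph))
    return infections


def simulate_community(
    config: SimulationConfig,
) -> tuple[GroundTruth, SimulatedDataset]:
    """Generate a synthetic community and its full sequencing dataset.

    Deterministic: the same config (including its seed) yields an
    identical dataset byte-for-byte when written to disk.
    """
    cfg = config
    cfg.validate()
    rng = np.random.default_rng(cfg.seed)

    width = max(3, len(str(cfg.n_hosts)))
    pwidth = max(3, len(str(cfg.n_phages)))
    hosts = pd.DataFrame(
        {
            "mag_id": [f"B{i:0{width}d}" for i in range(1, cfg.n_hosts + 1)],
            "length_kb": rng.uniform(*cfg.host_length_kb, size=cfg.n_hosts),
        }
    )
    base = rng.lognormal(cfg.host_abundance_mu, cfg.host_abundance_sigma, cfg.n_hosts)
    for ci, cond in enumerate(cfg.conditions):
        shift = (
            np.ones(cfg.n_hosts)
            if ci == 0
            else rng.lognormal(0.0, cfg.condition_abundance_sigma, cfg.n_hosts)
        )
        hosts[f"abundance.{cond}"] = base * shift

    phages = pd.DataFrame(
        {
            "phage_id": [f"v{i:0{pwidth}d}" for i in range(1, cfg.n_phages + 1)],
            "length_kb": rng.uniform(*cfg.phage_length_kb, size=cfg.n_phages),
            "lifestyle": np.where(
                rng.random(cfg.n_phages) < cfg.p_lysogenic, "lysogenic", "lytic"
            ),
        }
    )

    infections = _draw_infections(cfg, rng, hosts, phages)

    # phage physical abundance: sum of copies carried by its hosts
    h_ab = {
        (r["mag_id"], cond): r[f"abundance.{cond}"]
        for _, r in hosts.iterrows()
        for cond in cfg.conditions
    }
    for cond in cfg.conditions:
        col = np.zeros(cfg.n_phages)
        idx = {p: i for i, p in enumerate(phages["phage_id"])}
        for inf in infections:
            if inf.condition == cond:
                col[idx[inf.phage_id]] += inf.true_vph * h_ab[(inf.mag_id, cond)]
        phages[f"abundance.{cond}"] = col

    truth = GroundTruth(hosts=hosts, phages=phages, infections=infections)

    entities = pd.concat(
        [
            hosts[["mag_id", "length_kb"]]
            .rename(columns={"mag_id": "entity_id"})
            .assign(entity_type="mag"),
            phages[["phage_id", "length_kb"]]
            .rename(columns={"phage_id": "entity_id"})
            .assign(entity_type="phage"),
        ],
        ignore_index=True,
    )[["entity_id", "entity_type", "length_kb"]]

    lengths = dict(zip(entities["entity_id"], entities["length_kb"]))
    all_ids = entities["entity_id"].tolist()
    n_ent = len(all_ids)
    iu = np.triu_indices(n_ent, k=1)

    reps = [f"r{j}" for j in range(1, cfg.n_replicates + 1)]
    link_tables: dict[tuple[str, str], LinkTable] = {}
    mg_cov: dict[str, pd.DataFrame] = {}
    mt_cov: dict[str, pd.DataFrame] = {}

    for ci, cond in enumerate(cfg.conditions):
        cond_infections = [i for i in infections if i.condition == cond]
        for rep in reps:
            table = LinkTable(replicate_id=rep, condition=cond, lengths=dict(lengths))
            # intra-MAG connectivity
            lam_intra = (
                cfg.intra_link_rate
                * hosts[f"abundance.{cond}"].to_numpy()
                * hosts["length_kb"].to_numpy() ** 2
            )
            intra_draw = rng.poisson(lam_intra)
            table.intra = dict(zip(hosts["mag_id"], map(int, intra_draw)))
            # true phage-host links
            for inf in cond_infections:
                lam = (
                    cfg.inter_link_efficiency
                    * inf.true_vph
                    * h_ab[(inf.mag_id, cond)]
                    * lengths[inf.phage_id]
                    * lengths[inf.mag_id]
                )
                n = int(rng.poisson(lam))
                if n > 0:
                    table.add(inf.phage_id, inf.mag_id, n)
            # uniform background noise over unordered entity pairs
            if cfg.noise_link_rate > 0:
                noise = rng.poisson(cfg.noise_link_rate, size=len(iu[0]))
                nz = np.nonzero(noise)[0]
                for k in nz:
                    a, b = all_ids[iu[0][k]], all_ids[iu[1][k]]
                    table.add(a, b, int(noise[k]))
            link_tables[(cond, rep)] = table

            sid = f"{cond}_{rep}"
            mg_cov[sid] = _coverage_frame(
                cfg, rng, sid, entities, hosts, phages, cond, kind="dna"
            )
            mt_cov[sid] = _coverage_frame(
                cfg, rng, sid, entities, hosts, phages, cond, kind="rna",
                activity_multiplier=cfg.condition_activity_multipliers[ci],
                dna_presence=mg_cov[sid],
            )

    transcripts = _args_matrix(cfg, rng, hosts, reps)

    dataset = SimulatedDataset(
        entities=entities,
        link_tables=link_tables,
        metagenome_coverage=mg_cov,
        metatranscriptome_coverage=mt_cov,
        transcripts=transcripts,
        config=cfg,
    )
    return truth, dataset


def _coverage_frame(
    cfg, rng, sample_id, entities, hosts, phages, cond, kind,
    activity_multiplier: float = 1.0, dna_presence: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """One sample's coverage table.

    Present entities get breadth strictly above 0.5 and depth proportional
    to abundance with log-normal noise; absent entities get breadth
    strictly below 0.5 and zero depth — the 50%-breadth decision boundary
    is therefore exercised but never straddled by construction.
    """
    ab = pd.concat(
        [
            hosts.set_index("mag_id")[f"abundance.{cond}"],
            phages.set_index("phage_id")[f"abundance.{cond}"],
        ]
    ).reindex(entities["entity_id"])
    sd = math.sqrt(math.log(1 + cfg.depth_noise_cv**2))
    noise = rng.lognormal(-sd**2 / 2, sd, len(ab))
    depth = ab.to_numpy() * cfg.depth_per_abundance * noise
    lifestyle = (
        pd.concat(
            [
                pd.Series("host", index=hosts["mag_id"]),
                pd.Series(phages["lifestyle"].to_numpy(), index=phages["phage_id"]),
            ]
        ).reindex(entities["entity_id"]).to_numpy()
    )
    if kind == "rna":
        factor = np.where(
            lifestyle == "host",
            1.0,
            activity_multiplier
            * np.where(lifestyle == "lysogenic", cfg.lysogenic_activity_factor, 1.0),
        )
        dropout = (rng.random(len(ab)) < cfg.p_transcript_dropout) & (lifestyle != "host")
        depth = depth * factor * (~dropout)
    present = ab.to_numpy() > 0
    breadth = np.where(
        present,
        0.5 + 0.5 * rng.beta(5.0, 2.0, len(ab)),
        0.5 * rng.beta(2.0, 5.0, len(ab)),
    )
    depth = np.where(present, depth, 0.0)
    df = pd.DataFrame(
        {
            "entity_id": entities["entity_id"].to_numpy(),
            "sample_id": sample_id,
            "breadth": breadth,
            "mean_depth": depth,
            "library_size": cfg.library_size,
        }
    )
    if kind == "rna" and dna_presence is not None:
        # upstream mapping is restricted to DNA-present entities
        dna_ok = dna_presence.set_index("entity_id")["breadth"] > 0.5
        df = df[df["entity_id"].map(dna_ok).fillna(False)].reset_index(drop=True)
    return df


def _args_matrix(cfg, rng, hosts, reps) -> pd.DataFrame:
    """argS-proxy transcript relative abundances, samples x proxies.

    A low-rank latent-factor model on log abundances induces the
    correlation structure co-occurrence inference needs. One proxy per
    MAG by default; MAGs listed in ``duplicate_proxy_mags`` contribute a
    second, noisier copy of their proxy (some real MAGs carry two argS
    genes).
    """
    proxies = [f"argS_{m}" for m in hosts["mag_id"]]
    base_log = {
        f"argS_{r['mag_id']}": np.log(
            np.array([r[f"abundance.{c}"] for c in cfg.conditions])
        )
        for _, r in hosts.iterrows()
    }
    loadings = {p: rng.normal(0.0, 0.8, cfg.n_latent_factors) for p in proxies}
    samples, rows = [], []
    for ci, cond in enumerate(cfg.conditions):
        for rep in reps:
            samples.append(f"{cond}_{rep}")
            f = rng.normal(0.0, 1.0, cfg.n_latent_factors)
            row = []
            for p in proxies:
                row.append(
                    math.exp(
                        base_log[p][ci] + loadings[p] @ f + rng.normal(0.0, 0.3)
                    )
                )
            rows.append(row)
    mat = pd.DataFrame(rows, index=pd.Index(samples, name="sample_id"), columns=proxies)
    for mag in cfg.duplicate_proxy_mags:
        src = f"argS_{mag}"
        if src not in mat.columns:
            raise ValueError(f"duplicate_proxy_mags references unknown MAG {mag!r}")
        mat[f"{src}.2"] = mat[src].to_numpy() * rng.lognormal(0.0, 0.3, len(mat))
    return mat.div(mat.sum(axis=1), axis=0)  # relative abundance per sample


def truth_pair_set(truth: GroundTruth, condition: str) -> set[tuple[str, str]]:
    """The exact set of (phage_id, mag_id) infections active in a condition.

    The oracle for precision/recall of the detection pipeline.
    """
    known = {
        c.split(".", 1)[1] for c in truth.hosts.columns if c.startswith("abundance.")
    } | {i.condition for i in truth.infections}
    if known and condition not in known:
        raise KeyError(f"unknown condition {condition!r}; have {sorted(known)}")
    return {
        (i.phage_id, i.mag_id) for i in truth.infections if i.condition == condition
    }
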