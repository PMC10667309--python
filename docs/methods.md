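# Methods

## Problem and model

Hi-C proximity ligation crosslinks DNA molecules that are physically
co-located in a cell before sequencing chimeric junction fragments. In a
soil metagenome, a read pair joining a viral contig to a contig of a
metagenome-assembled genome (MAG) is direct evidence that the phage's DNA
was inside that host cell at sampling time. `hicphage` turns per-replicate
tables of such links into quality-filtered phage–host pairs, estimates of
infection intensity, infection networks, and treatment comparisons.

Two quantities drive the analysis. For a candidate pair of viral contig
*v* and MAG *h* in one replicate, with Hi-C link count *L*, the phage's
total links to all MAGs ΣL(v), and normalized abundances *V* (phage) and
*H* (host, mean read depth normalized by length and library size):

* **Viral copies per host cell**: VPH = (V/H) · (L/ΣL(v)). The abundance
  ratio scales copies per cell; the link share apportions the phage's
  abundance across its candidate hosts.
* **Connectivity ratio**: R′ = (D_VH/D_H) · (H·ΣL(v))/(V·L), where
  D_VH = L/(len_v·len_h) and D_H = intra/len_h² are Hi-C links per kb² of
  the pair and of the MAG to itself ("intra" counts links between distinct
  contigs of the same MAG). R′ compares the pair's link density to the
  host's internal link density after removing the VPH scale; the algebraic
  identity R′·VPH = D_VH/D_H holds exactly and is enforced by tests.
  Note R′ is independent of the pair's own L (it cancels): it measures how
  consistent the pair's connectivity is with the host's internal density,
  not how many links the pair has.

## Filtering cascade

1. **Round 1** (per candidate): L ≥ 2, R′ ≥ 0.1, intra-MAG connectivity
   ≥ 10. Thresholds are inclusive; the R′ comparison allows 1e-9 relative
   slack so a candidate exactly on the boundary is not lost to binary
   floating-point rounding.
2. **ROC threshold scan** (per Hi-C library, i.e. per condition ×
   replicate): scans every unique score value t and keeps candidates with
   score ≥ t, maximizing f(t)+g(t), where f is the fraction of phages
   retaining at least one host and g the fraction of links removed; ties
   resolve to the smallest t. The score defaults to R′ (L is selectable).
   The scan runs within each library rather than on the pooled replicates:
   pooling counts each biological link once per replicate in g while f
   needs only one copy, which biases the optimum toward discarding
   replicate duplicates of true links.
3. **Relative-count (80%) rule** (per condition × phage): a (phage, MAG)
   link whose count — averaged over the replicates in which the pair
   appears — is strictly below 80% of the phage's strongest averaged link
   is dropped. This is the main guard against sporadic background links
   and, by construction, demotes weak secondary hosts of generalists.
4. **Promiscuity adjustment**: phages linked to more than 20% of all MAGs
   in a replicate are flagged as likely false-positive-rich and removed by
   default; the flag report is always emitted so the policy can be
   overridden.

Survivors are collapsed to (vOTU × dereplicated host population ×
condition) infection pairs carrying the set of supporting replicates.
vOTUs come from greedy centroid clustering at 95% ANI / 85% aligned
fraction (AF computed on the shorter sequence, per the centroid workflow
convention; candidates are compared to cluster representatives only, and
length ties in the scan order break lexicographically by id). Host
populations come from the same greedy procedure on a pairwise identity
table at 99%. Per-host VPH is the sum of VPH over the host's surviving
phage links within a replicate (one value per linked host; unlinked hosts
yield no data point).

## Synthetic community

The simulator generates the study design the pipeline expects: host MAGs
with log-normal abundances (μ=0, σ=1), phage contigs with known host
ranges, and 3 replicates in each of two conditions ("pre" and "post" a
drying treatment). Defaults: 100 hosts (2–6 Mb), 150 phages (10–80 kb),
20% generalists with 2–3 hosts. Per active infection the true VPH is
log-uniform on (0.2, 2.0), coupled to log host abundance with slope −0.41
pre and 0.089 post (log-normal jitter, SD 0.4 in ln units) and multiplied
by 1.6 post, so the expected qualitative contrasts — a negative
VPH–abundance relationship before drying, none after, and a higher mean
VPH after — have a known generative counterpart. An infection is active
in both conditions with probability 0.30, otherwise in exactly one,
emulating the observed low overlap of phage communities across the
treatment.

Link counts are Poisson draws at the entity level:

* intra-MAG: rate 2×10⁻⁵ · abundance · length_kb² (≈180 links for a
  median-abundance 3 Mb MAG, comfortably above the intra ≥ 10 filter while
  letting rare low-abundance hosts fail it);
* phage–host: rate 2×10⁻⁴ · VPH · host abundance · len_v · len_h
  (≈10–40 links for typical pairs, so the L ≥ 2 filter bites only in the
  weak tail);
* background noise: rate 0.05 per unordered entity pair, uniform. No
  published generative model for Hi-C background exists; the uniform
  background is an assumption, chosen so that noise pairs occasionally
  reach L = 2 and the second-round filters have real work to do.

Coverage tables give present entities breadth 0.5+0.5·Beta(5,2) (always
above the 50% detection cutoff) and absent entities 0.5·Beta(2,5) (always
below), with depth proportional to abundance under ~10% log-normal noise —
the detection boundary is exercised but never straddled, because a
simulated truth that itself flickers across the boundary would make
recovery unmeasurable. Phage abundance is defined as the summed copies
carried by its hosts (Σ VPH·H); free phage particles are not modeled, so
estimated VPH is unbiased by design. Transcript activity multiplies
abundance by a condition factor (1.0 pre, 0.3 post) and a lifestyle factor
(lysogenic phages at 0.2), with 20% dropout. The argS proxy matrix uses a
3-factor log-linear latent model to induce co-occurrence structure; an
option duplicates a MAG's proxy to emulate genomes carrying two argS
copies.

What passing recovery tests show — and do not show. The simulator's world
is exactly the world the estimators assume (consistent abundances, no free
phage, no chimeric assembly errors, no shared repeats between phage and
host genomes). Passing precision/recall and VPH-recovery tests therefore
validates the implementation and the filter logic, not the biological
error rates one would see on real soil data, where repeats, binning errors
and free phage DNA violate these assumptions.

Under the default conditions with seed 1 the pipeline reaches precision
≈0.98, recall ≈0.81 and Spearman(estimated, true VPH) ≈0.97 over true
positives (recomputed by `scripts/acceptance.py`; recall is dominated by
the 80% rule demoting generalists' weaker secondary hosts, which is a
property of the method, not an implementation artifact). With the noise
rate at 0 every surviving candidate is a true infection and precision is
exactly 1.0.

## Other numerical and design choices

* **Voting rule**: a contig is viral iff ≥2 of the three detection tools
  call it viral, or exactly one does and CheckV rates it
  complete/high/medium. A tool's sub-threshold call counts as "not viral",
  not as an abstention.
* **Spacer matching**: full-length ungapped alignment, both strands,
  ≤1 mismatch and ≥95% identity (both conditions required — an 18-nt
  spacer with one mismatch is 94.4% identical and fails). Best hit only
  per spacer: fewest mismatches, then longest contig, then smallest id.
  Minimum spacer length 18 nt.
* **Detection**: presence iff breadth > 0.5 strictly ("more than half").
  The per-million abundance scale is a display constant; every reported
  quantity is a ratio. The breadth rule applies to DNA only; RNA activity
  is depth > 0 among DNA-present entities.
* **CLR network**: mutual information on equal-frequency (rank) bins,
  ⌈√n_samples⌉ bins; z-scores within each row excluding the diagonal;
  CLR score √(max(z_ij,0)² + max(z_ji,0)²). Top 200 edges, or the
  95th-percentile count when the matrix has fewer pairs than requested;
  score ties at the boundary are all kept and the applied rule is recorded
  in the output.
* **GENIE3-style network**: extremely randomized trees (100 trees,
  √p features, no bootstrap — hence invariant to sample order) per target;
  importances are directed edge weights; top 5% of directed pairs kept.
  Tree count and subsampling are documented, seeded configuration values.
* **Centrality**: unnormalized shortest-path betweenness on unweighted
  edges (edge weights are retained but not used for paths); degree is
  total degree on directed networks; ranks use competition ranking (ties
  share the smaller rank) so strict orderings like "second and third most
  central" are reproducible.
* **t-tests**: Welch (unequal variance) two-sided by default, pooled
  variance available; degenerate zero-variance groups short-circuit to
  p = 1 (equal means) or p = 0 (separated). No multiple-testing
  correction, matching the per-comparison p < 0.05 convention; the
  manifest records how many tests were run.
* **Regression**: OLS of log10 VPH on log10 host abundance (scale is a
  config flag surfaced in the manifest); perfect fits report F-test p = 0
  rather than NaN.
* **Determinism**: every output table is sorted and written with a fixed
  float format; the report bundle is a pure function of (inputs, config,
  seed) and reruns are byte-identical.

## Problem sizes

The bundled test and acceptance runs use the default 100×150 community
(≈250 entities, ≈30k potential link pairs per replicate, six replicates)
and a 15×20 community for fast end-to-end checks; oracle comparisons use
instances of ≤50 candidates, ≤10 cluster items and ≤8-node graphs where
exhaustive enumeration is exact.

## Known limitations

* Read-level processing (alignment, duplicate marking) is consumed as
  already-aggregated tables; the read-pair aggregation operation is
  exercised on hand-written records only.
* MAG dereplication consumes a supplied pairwise-identity table; ANI
  estimation between genomes is out of scope.
* The infection network treats support per condition independently; no
  temporal model links the two conditions.
* Lysogeny vs lysis is inferred indirectly (VPH shifts, activity,
  abundance correlations); the package does not detect integrases or
  prophage boundaries.
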