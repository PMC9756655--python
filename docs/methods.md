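# Methods

## Enzyme-group model

Proteins are classified from domain content alone. The decision order is
GGDEF∧EAL → hybrid, then GGDEF, then EAL, then HD-GYP, then NONE. Two
modeling commitments deserve note:

- **The HD-GYP call is motif-gated.** An HD-superfamily hit (PF01966) is
  catalytically meaningful only when the protein carries the
  `HHExxxxxGYP` signature. The motif is read literally as the regular
  expression `HHE.{5}GYP`, case-insensitive, with `x` matching any
  residue including the ambiguity code X. By default the whole sequence
  is scanned; `motif_scope="hd_hit"` restricts the scan to HD hit
  intervals ± 10 aa for users who want the signature anchored to the
  domain. Nothing ties the motif to a position in the protein, because
  the signature itself is positional (it spans the HD active-site
  region), and on real annotations the whole-sequence scan and the
  anchored scan agree except for truncated hits.
- **GGDEF/EAL dominance over HD.** A protein with GGDEF or EAL never
  lands in the HD-GYP class, whatever its HD content; the HD domain is
  then auxiliary (recorded under the name `HD`). Consequently a missing
  sequence is an error only when the class actually hinges on the motif
  check — an HD hit with no GGDEF/EAL and no sequence raises; an HD hit
  riding on a GGDEF protein does not need one.

Domain identity elsewhere is the Pfam accession when present, else the
name; PAS subfamilies (PAS_3, PAS_4, …) stay distinct. Repeated copies of
a domain in one sequence count once, both for classification and for all
auxiliary-domain statistics.

## Chromosome geometry

Coordinates are 1-based inclusive (GenBank/GFF3 convention); wrap-around
CDSs on circular replicons are normalized to `start..end+L` at read time.
The gene's representative point is the **CDS midpoint** — strand-neutral
and stable for long genes; a start-anchored variant would shift every
position by half a gene length, well under one percentage point on a
megabase chromosome. Strand is recorded but ignored positionally.

*ter* is placed opposite *ori*: `ter = ((ori − 1 + ⌊L/2⌋) mod L) + 1`.
Normalized position is the clockwise arc fraction from *ori* in percent;
it is exactly rotation-invariant and maps reflection about the ori–ter
axis to `v ↦ 100 − v`.

### GC-skew origin estimation

The per-base cumulative skew S(i) = Σ_{j≤i} sign(base_j) (G → +1,
C → −1, A/T → 0) attains its minimum at the leading/lagging strand
switch. The estimator localizes the **global minimum of the per-base
curve** and reports the midpoint of the window (default 1 kb) containing
it; localizing on the windowed curve alone would add up to half a window
of avoidable quantization error. Ambiguity is judged on the windowed
curve: when the two lowest circular local minima differ by less than 5%
of the full skew range (including the flat-curve degenerate case), the
call is flagged ambiguous and the replicon is excluded from positional
analysis. The estimator is a deliberately simple desk-scale origin
finder; curated *ori* tables should be supplied whenever published calls
exist. Sequences shorter than 10 windows are rejected.

## Distribution statistics

- **Circular KDE.** Gaussian kernels on a 512-point grid over [0, 100);
  wrap handled by replicating the sample at −100/0/+100 and renormalizing
  the trapezoidal integral over one period to 1 (enforced to 1e−6).
  Default bandwidth is Silverman's rule, `0.9·min(sd, IQR/1.34)·n^{−1/5}`,
  computed on the unwrapped sample; a user override is the only other
  smoothing control.
- **Two-sample KS.** Computed **linearly on the ori-anchored scale**: the
  scale is anchored at a biologically fixed point, so the usual
  rotation-invariance objection to linear KS on circular data does not
  apply. D is the ECDF sup over all sample points; the asymptotic p comes
  from the limiting Kolmogorov distribution at √(en)·D with
  en = n₁n₂/(n₁+n₂); exact-permutation p (full enumeration, ties counted
  as ≥) is available for n₁+n₂ ≤ 16. A Kuiper variant (V = D⁺ + D⁻,
  rotation-invariant) is provided for sensitivity analysis but is not the
  default. At n₁ = n₂ = 8 the asymptotic and exact p agree within 0.05.
- **Medians** use linear interpolation at even n (so reported medians may
  end in .5 where an integer convention would not).
- **Ratios** with zero denominators are undefined and excluded from genus
  means rather than imputed. Note that the Fig-3-style estimator — mean
  over genomes of per-genome count ratios — is biased for the ratio of
  the underlying means when counts are small (E[G/E | E>0] ≠ E[G]/E[E]
  for Poisson counts); at the default profile's count level the two
  coincide (≈ 2.0), which is part of why that level was chosen.
- **Spearman correlation** (size vs gene count, largest replicon only) is
  tie-corrected with p from the t-approximation; constant inputs return
  an undefined, flagged result.

## Replicon typing

Largest replicon → primary chromosome; any other replicon above the
cutoff (default 800,000 bp, configurable) → secondary chromosome; the
rest extrachromosomal. The cutoff is strict (`>`). Ties for largest are
broken lexicographically by replicon id and flagged. No biological
chromid/plasmid typing beyond the size rule is attempted.

## Synthetic-data generator

The generator emulates the pipeline's real-world inputs — Pfam-style
per-protein hit tables, GFF3 + FASTA annotations, a protein FASTA,
taxonomy and *ori* tables — with a JSON truth record. Planted structure
and defaults:

| knob | default | meaning |
|---|---|---|
| class_count_means | GGDEF 3.0, EAL 1.5, GGDEF_EAL 3.0, HD-GYP 0.5 | Poisson means per genome; GGDEF/hybrid dominant, EAL at half the GGDEF level (mean ratio 2), HD-GYP the smallest share |
| position_models | EAL ~ WN(5, 6); GGDEF ~ ⅓WN(25,5)+⅓WN(50,5)+⅓WN(75,5); hybrid ~ WN(3, 7); HD-GYP ~ WN(50, 30) | wrapped-normal mixtures on [0,100): EAL near *ori*, GGDEF tri-modal mid-replichore and at *ter* |
| replicon_length_bp | 4,000,000 | primary-chromosome length |
| motif_rate | 0.8 | fraction of single-HD proteins carrying the motif; the rest become NONE-class decoys |
| secondary_chromosome_prob / secondary_gene_fraction | 0.15 / 0.3 | occasional > 800 kb secondary replicon and the chance a gene lands there |
| aux_min_length | GGDEF 275, EAL 375, hybrid 450, HD-GYP 350 aa | minimum length of aux-bearing proteins |
| short_noaux_fraction | 0.49 | aux-free proteins drawn below the class threshold |
| skew_gc | (0.35, 0.15) | G/C probabilities on the G-rich half; swapped on the other, switch at the planted *ori* |

Gene nt coordinates anchor at `round(pos/100·L)` rotated by the planted
*ori* and are resolved greedily around the circle (starting after the
largest anchor gap, ≥ 50 bp spacing); infeasible configs raise rather
than truncate. The nudging perturbs realized positions by ≪ 0.1% on
megabase replicons. Aux-bearing protein lengths are drawn at or above the
class threshold with the group minimum pinned **exactly at** the
threshold, so the length-threshold analysis recovers the planted value
exactly; `planted_length_group` exposes the same machinery with exact
group sizes. HD proteins get random amino-acid sequences with the motif
embedded (or verified absent).

Deliberately **not** emulated: real ORFs under the gene coordinates,
codon usage, GC content beyond the skew switch, e-value realism, and
phylogenetic correlation between genomes. Passing recovery tests
therefore demonstrates the correctness of the estimators under the
planted generative family, not robustness to annotation noise,
mis-called domains, or lineage structure in real data.

## Determinism and problem sizes

All randomness flows through one `numpy` generator per run, seeded from
the config; generated datasets and result tables are byte-identical
across reruns (rows sorted, fixed column order, run parameters in the
JSON manifest). Tests and the acceptance script use deliberately modest
problem sizes — 100 kb–300 kb replicons, 5–200 genomes, n = 150 per
positional group, 50–200 replicates for mode/power estimates — chosen so
the whole suite runs on a laptop-class single core while keeping every
recovery band comfortably wider than the Monte-Carlo error at those
sizes. Single-draw KDE argmaxes carry ~2-point sampling noise at n = 150;
mode-recovery checks therefore report the median argmax over replicate
draws.

## Known limitations

- The GC-skew estimator has no DnaA-box or indicator-gene logic; on real
  chromosomes with weak or structured skew it will flag ambiguity more
  often than a dedicated origin finder resolves it.
- The GFF3 reader handles the CDS subset the pipeline needs (one feature
  per protein, `protein_id`/`ID` attributes); it is not a general GFF3
  parser.
- Protein lengths inferred from CDS spans (when no protein FASTA is
  given) assume a single uninterrupted frame including the stop codon.
- The exact KS test is limited to 16 pooled observations by design; past
  that the asymptotic p is used even when `ks_method="exact"` is
  requested at the pipeline level.
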