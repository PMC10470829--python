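# Methods

This note documents the models and procedures implemented by
`ball_subtyper`, their assumptions and tunable parameters, what the
synthetic-data generator does and does not emulate, and the design choices
made where the design was genuinely open.

## Depth model and copy-number profiling

A bulk leukemia sample is modelled as a mixture of tumor cells at fraction
*f* (purity, supplied from the blast percentage — no purity inference is
attempted) and diploid normal cells. A region at integer tumor copy number
*c* then has expected sequencing depth proportional to

    w(c, f) = (2(1 − f) + c·f) / 2,

relative to the diploid baseline. Profiling proceeds as in CGH-style WGS
review:

1. **Binning** — fragments are counted by the bin (default 1 kb) holding
   their leftmost mapped base. The default yields ≈100 fragments/bin at
   30× with 2×150 bp reads, so Poisson noise per probe is small.
2. **Pooling** — 20 consecutive bins pool into one probe (20 kb); the
   probe value is log2(probe mean / genome-wide mean). The genome mean is
   drawn at height 0 as the nominal diploid line.
3. **Baseline re-centring** — in aneuploid genomes the genome-wide mean is
   not the disomic level (a 55-chromosome hyperdiploid genome pushes
   disomic chromosomes to ≈ −0.26). The workflow this package automates
   adjusted that threshold manually; here the offset is computed as the
   length-weighted centre of the largest cluster of per-chromosome medians
   (cluster tolerance 0.1 log2 units; ties break toward the cluster
   nearest 0), subtracted from all probes, and logged in every report. If
   every chromosome forms its own cluster the track is flagged ambiguous
   and left uncentred. Note that at toy scale the offset is *not* small:
   one trisomy among five equal chromosomes biases the mean by 10%, so the
   correct offset is log2(2/2.2) ≈ −0.138 — the invariant is that disomic
   chromosomes end at ~0, not that the offset is ~0.
4. **Copy states** — each chromosome's state is the integer c (0–8)
   whose level log2 w(c, f) is nearest the chromosome median (equivalent
   to midpoint thresholds); c = 0 at f = 1 is handled with a −5 cap.
   Sub-chromosomal segments come from runs of ≥3 consecutive probes
   assigned to a different state — a run-length rule at the granularity of
   the visual inspection it replaces, deliberately not circular binary
   segmentation.
5. **Ploidy classes** — the chromosome count (sum of states) maps to
   near-haploid (<30), low hypodiploid (30–39), diploid range (40–50),
   high hyperdiploid (51–67), near-triploid (58–80) and near-tetraploid
   (81–103). The HeH/near-triploid overlap resolves to HeH unless a
   duplicated-hypodiploid signature is flagged, in which case the call is
   ambiguous — the package encodes the ambiguity rather than attempting a
   duplicated-genome detector, beyond the allele-evidence route below.
   Classes are only assigned when the reference models a full karyotype
   (diploid count ≥ 40); the 5-chromosome toy genome reports raw counts.
6. **Focal CNAs** — per shortlist locus, the median of overlapping probes
   (≥3 required; a zero-coverage masked probe counts as copy-0 evidence,
   since at high purity a biallelic deletion *is* a coverage hole) gives a
   local state; a difference from the chromosome state is reported as
   deletion (biallelic at state 0) or amplification. A PAR1 deletion is
   additionally emitted as the fusion P2RY8::CRLF2. iAMP21 is a ≥3-probe
   run at state ≥5 (≥3 extra copies) on chr21 while the whole chromosome
   stays below that state; boundaries are the run's first/last probe, so
   recovery is tested to within one probe (20 kb).
7. **CNN-LOH / UPD** (paired mode only) — at germline-heterozygous sites,
   a chromosome with median |BAF − 0.5| > 0.3 while |median log2| < 0.1 is
   allele-imbalanced at neutral depth; whole-chromosome extent is reported
   as UPD, a single-arm signal as CNN-LOH. Requires ≥20 sites per
   chromosome. In leukemia-only mode the operation is signalled
   unavailable, never silently skipped.

## Targeted IGH::DUX4 detection

DUX4 lies inside the D4Z4 macrosatellite, so the partner side of an
IGH::DUX4 junction maps ambiguously (and at low mapping quality) across
the array copies — genome-wide callers drop it. The targeted detector
filters by *region*, not quality:

- anchor extraction: fragments with ≥1 primary read overlapping the IGH
  anchor (any overlap, half-open intervals; `min_mapq` defaults to 0
  because requiring quality on the repetitive side destroys sensitivity)
  that are discordant — not proper-pair flagged, or mate on another
  chromosome, or |insert| > mean + 4 sd;
- target linking: of those, fragments whose mate's primary alignment
  overlaps a target region (clause i) or that carry a secondary alignment
  overlapping one (clause ii). A fragment qualifying via both clauses is
  counted once (set semantics; the breakdown attributes it to clause i).
- calling: positive iff the supporting-pair count reaches the threshold.
  **Default threshold: 10 pairs.** No cutoff is prescribed by the workflow
  this reimplements; observed positives are ≥31 pairs and negatives ≤6 at
  90× (≤3 at 30×), so 10 sits in the gap with margin on both sides, and
  the value is configurable and recorded in every call.

The GRCh37 anchor (14:106032614–107288051) and targets (4:190988100–
191007000, 10:135477000–135500000, GL000228.1:7000–115000) ship as
defaults for real data; toy references carry their own anchor and a
two-copy target set on distinct chromosomes to exercise both clauses.

## SV filtration cascade

Fixed order, each stage (kept, dropped) with a conserving ledger:

1. population-frequency filter: drop iff cohort AF **strictly** above
   0.02 ("above" is strict; AF = 0.02 is kept; unannotated calls are
   kept — they cannot exceed the threshold);
2. artifact-database filter: same rule on the locally-observed artifact
   frequency (call-level frequency assumed);
3. germline subtraction (paired mode): drop a leukemia call matching a
   germline call of the same SV type with both breakpoints within 1 kb
   (window assumed; the source workflow states no criterion). A dropped
   call hitting the shortlist logs a warning: a pre-relapse "remission"
   sample can silently subtract a true driver, and the warning — not a
   changed call — is the guard;
4. shortlist intersection: keep iff either breakpoint lies in a shortlist
   locus extended by a strand-aware 5 kb upstream pad. The pad generalises
   an ad-hoc single-gene fix: breakpoints immediately upstream of a
   kinase gene produced a missed ABL-class fusion under body-only
   intersection, so the pad is on by default for every entry.

The frequency and artifact filters commute; germline subtraction and the
shortlist do not commute with them, hence the enforced order. Fusion
naming takes breakpoint 1 as the 5′ partner (planted and parsed calls
follow that convention); calls hitting the shortlist on one side only get
"GENE-r(partner coords)" labels; DEL/DUP entirely inside one gene are
intragenic events, not fusions, and are folded into the CNA inventory.
Multi-caller merging is reduced to optional dedup of same-type calls
within 50 bp (first caller wins).

The exact shortlist used clinically is not public; the shipped defaults
are the gene-name vocabulary (`fixtures/shortlist_genes.txt`) plus
toy-reference coordinates, and the shortlist is always a replaceable BED
input, never hard-coded logic.

## Subgroup rule engine

Rules are data (serializable predicates), evaluated totally and
deterministically. Tiers: 8 mandatory rules (ETV6::RUNX1, TCF3::PBX1,
Ph-positive, KMT2A-r, ABL-class = ABL1/ABL2/PDGFRB/PDGFRA/CSF1R fusion
with non-BCR partner, iAMP21, HoL incl. near-haploid, HeH), 8 emerging
rules (CRLF2-r = IGH::CRLF2 or P2RY8::CRLF2; ZNF384-r; MEF2D-r; IGH::ID4;
DUX4-r = targeted-assay positive; ETV6::RUNX1-like = ETV6::IKZF1 or
FUS::ERG or ETV6 deletion + IKZF1 fusion; PAX5-alt = PAX5 fusion,
deletion or amplification; PAX5 P80R, shipped disabled since no case
defines it in the source workflow), and one suspect rule (isolated ERG
deletion → DUX4-suspect, evaluated only when nothing class-defining
fired). Precedence: mandatory before emerging; within mandatory, fusions
before ploidy classes (a Ph-positive hyperdiploid case is Ph-positive
first, HeH co-reported); within emerging, fusion-defined subgroups before
PAX5-alt, which is frequently a secondary alteration and is co-reported,
never suppressed. `confirm_dux4` upgrades a suspect or unclassified call
to DUX4-r on a positive targeted result and changes nothing on a negative
one. The IKZF1-plus flag (IKZF1 deletion + deletion of CDKN2A/B, PAX5 or
PAR1, without ERG deletion) encodes its published definition as
configurable data — it originates outside the reimplemented workflow.

## Down-sampling

Fragment-level, so mates are never separated (discordant-pair evidence
depends on intact pairs): systematic keep-1-in-3 by sorted fragment id
(deterministic; retains ⌈n/3⌉), and a seeded per-fragment Bernoulli mode.
The source description conflates "randomly discarding" with "every third
read"; both readings are exposed, neither is claimed to be the original
procedure.

## Synthetic data: what it emulates, and what it does not

The generator reproduces the *statistical structure* the pipeline reads:
depth proportional to w(c, f) per chromosome and per focal interval
(deterministic fragment counts, uniform positions, normal insert model
350 ± 50 bp, 2×150 bp, defaults matching the emulated libraries — the
insert sd is an assumption, not a reported value), discordant pairs
spanning planted translocation junctions, an exact planted number of
anchor↔target support pairs split ~50/50 between the mate and
secondary-alignment mechanisms, fragment-level allele flags at planted
SNV sites, and binomial allele counts at germline-het sites (UPD shifts
BAF by ±f/2). Decoy SV calls draw population AFs from a 60/40
common/rare mixture (common ~U(0.02, 0.5), rare ~U(0, 0.02)), chosen so
the 0.02 filter's effect is visible and tunable; 15% of decoys also carry
an artifact frequency ~U(0, 0.1).

Deliberately not emulated: base calls and quality scores (the SNV assay
consumes fragment-level allele annotations; `min_baseq` is accepted for
interface parity but inert on synthetic data), sequencing error,
duplicates, GC/mappability bias, real repeat sequence, SNV/indel
background, and SV-caller behaviour (planted calls appear in the emitted
VCF by construction; targeted fusions are *excluded* from it by default,
reproducing the repetitive-region blind spot that motivates the targeted
detector). Passing tests therefore validate the downstream logic under
idealised signal, not caller sensitivity or alignment artifacts on real
data.

Two scale corrections follow from the 10 Mb toy genome: decoy breakpoints
avoid the named gene loci (+6 kb), because the toy shortlist covers ~20%
of the genome versus <0.1% in reality, and unconstrained decoys produced
coincidental two-driver-gene breakends that real data essentially never
does; and ploidy classes are only assigned on the 23-chromosome
miniature genome, whose diploid count (46) matches the clinical modal
ranges.

## Validation cohort and problem sizes

The 12-sample cohort (`cohort.py`) plants one sample per mandatory and
emerging subgroup over the 23×400 kb genome at 90×, with the hardest
printed conditions included: ETV6::RUNX1 at tumor fraction 0.37 and
KMT2A::AFF1 at 0.14 (the lowest blast fractions the workflow validated),
and a DUX4 sample reachable only via the targeted assay (isolated ERG
deletion + 126 planted support pairs — one of the observed 90× support
counts, which also survives every-third down-sampling with margin, where
31 would land exactly at the threshold). Every sample is analysed at 90×
and again after down-sampling to ~30×. Desk-scale sizes throughout:
5×2 Mb and 23×400 kb genomes, 30–90× coverage, 10³ decoy SVs — chosen so
the full suite simulates millions of fragments in minutes while keeping
per-probe counting noise (σ ≈ 0.03 log2 units at 30×) far below the
smallest state separation the tests rely on (0.32 at f = 0.5).

## Known limitations

- Purity is an input; no ASCAT-style purity/ploidy grid search.
- The segment caller is a run-length rule; small or noisy events below
  3 probes (60 kb at defaults) are invisible — matching the intended
  granularity, but not a segmentation algorithm.
- Fusion 5′/3′ orientation uses the breakpoint-1 convention rather than
  full strand/orientation algebra; partner-order-sensitive rules treat
  gene pairs as unordered where the biology allows.
- Exon-level CNA annotation is carried from inputs, not computed (the toy
  genome has no exon model).
- The HeH vs duplicated-hypodiploid distinction relies on the ambiguity
  flag and paired-mode allele evidence only.
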