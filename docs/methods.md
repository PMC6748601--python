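# Methods

## The identity model

All comparisons operate in IMGT coordinates. A numbered chain is a map from
IMGT positions (1–128 plus lettered CDR3 insertions) to amino-acid residues;
two chains are compared position-by-position with no alignment step, because
the shared numbering already is the alignment. A *match* is a position
occupied in both chains with an identical residue. The identity of query *q*
and template *t* is the average of the two possible normalisations,

seqID = (m/L_q + m/L_t) / 2,

where lengths are occupied-position counts — not sequence spans and not
pre-numbering string lengths — so numerator and denominators live in the
same coordinate system. The two-sided average is deliberate: normalising by
only one length would let a short fragment embedded in a longer chain score
100%. Identity means identity: there is no substitution matrix, and the
unknown-residue placeholder `X` never produces a match (not even against
another `X`) — an unread residue is treated as evidence of nothing.

CDR-level modes compare the concatenated CDR1+2+3 (or CDR-H3 alone) and are
defined only when the loop lengths match loop-wise; incomparable pairs are
reported as "not comparable", which a best-match search treats as
ineligible rather than as 0%. With equal lengths the two normalisations
coincide and seqID reduces to m/L.

CDR boundaries default to the IMGT standard (CDR1 27–38, CDR2 56–65, CDR3
105–117) and are configurable via `RegionScheme` for sensitivity analyses.
Insertion codes follow the IMGT junction convention: ascending letters after
111, descending letters before 112, so the reading order of a long loop is
111, 111A, …, 112B, 112A, 112. A consequence asserted in the tests: for
equal-length loops, position-wise comparison equals plain string comparison
of the extracted loop.

Displayed identities are integer percents rounded half-up. Rounding is done
on the exact rational m-and-L representation (or on the shortest decimal
form of a bare float), because binary floating point misplaces .5
boundaries — 0.975 must display as 98.

## Search semantics

`best_match` is contractually exhaustive: it must return the same best
value, the same retained template and the same tie count as a plain scan
over every eligible template (`exhaustive_best_match`, kept in the package
as an independently implemented oracle and compared against the indexed
path in the tests). Ties are broken to the earliest template in repertoire
insertion order — reproducible with no extra keys — and `tie_count` retains
the fact that ties existed. Tie comparisons use exact `Fraction` arithmetic;
the vectorised full-chain scan resolves the float argmax back to exact
arithmetic over a 1e-9 candidate band before declaring a winner. "No
eligible template" is an explicit no-match result, never a silent zero.

The index accelerates without changing semantics: CDR modes prune by loop
length, which the comparability rule already makes lossless; a CDR-H3
exact-string hash resolves perfect matches directly (skipped when the query
loop contains `X`, which breaks the hash-equality ⇔ match-equality
correspondence); the full-chain mode, which admits no lossless cheap prune
under this metric, uses a dense uint8 residue-code matrix over the chain
partition's position vocabulary. A constant-memory streaming profile
(`streaming_best_matches`) performs one pass over a repertoire iterator with
an optional early-exit bound m ≤ min(L_q, L_t) ⇒ seqID ≤ (min/L_q +
min/L_t)/2, proven lossless by equivalence tests against the plain scan.

## Productivity filter

Repertoire ingest drops sequences that could not encode a functional
receptor. The rules are explicit and individually toggleable: a stop-codon
marker `*` anywhere in the raw sequence; conserved Cys missing at IMGT 104;
conserved Trp/Phe missing at 118; numbered coverage below 80% of the raw
sequence length. The reason string names the first failed rule, in that
order. These rules are this package's own operationalisation of
"unproductive"; external numbering tools apply their own internal criteria,
which are not published in detail, so exact agreement with any one tool is
not claimed.

## Classification and summarisation

INN suffix rules are applied case-insensitively as substring tests:
chimeric (`xizumab`/`ximab`) before humanized (`zumab`) before fully human
(`umab`); an explicit name list (default: muromonab, abagovomab,
racotumomab) overrides the suffix rules, since the oldest mouse antibodies
predate the suffix convention. Names matching no rule are reported as
`unknown` in batch mode rather than aborting a run.

Threshold predicates are evaluated on raw fractional identities (with a
one-sided 1e-12 tolerance at the threshold) when a live search produced
them, and on the integer percents themselves when the input is an
already-rounded table. The distinction matters: 113/119 displays as 95% but
is below a raw ≥ 0.95 cut. Summary percentages are printed with one decimal,
half-up. Report rows are ordered by descending best heavy-chain identity,
then name. Per-type strata report five-number summaries and flag types with
fewer than 5 members as small-sample. Source attribution counts the species
and study of the single retained (earliest-tie) best match per query and
mode; `tie_count` preserves the ambiguity that attribution choice hides.

## Synthetic repertoire generator

The generator emulates the gross structure of an OAS-style numbered
repertoire at the amino-acid level: a germline V scaffold (frameworks 1–3
with germline CDR1/2 of varying lengths), a CDR3 junction of random
composition and sampled length numbered with the IMGT insertion convention,
and a germline J tail (framework 4). On top of the germline assembly it
applies Poisson(shm_rate) point substitutions (somatic hypermutation
stand-in), independent per-residue substitutions at `error_rate`
(sequencing error stand-in), and, with probability `unproductive_fraction`,
one unproductive lesion (stop marker, broken Cys104, or broken Trp/Phe118).

Defaults, chosen once as plausible study conditions: CDR3 length ~
discretised Gaussian(mean 15, sd 3) on support 8–22, matching typical human
IMGT junction lengths; `shm_rate` = 5.0 substitutions per sequence, a
memory-compartment-like mutational load; `error_rate` = 1e-3 per residue,
the order of NGS error after consensus processing; `unproductive_fraction`
= 0 because the generator emulates post-filter repertoire data — filter
tests inject lesions explicitly. Germline scaffolds (5 V × 3 J per chain)
are shipped as JSON data; they are synthetic stand-ins with realistic
anchors and framework lengths, not real gene sequences. Random substitution
positions exclude the conserved anchors 104/118: the simulated reads
represent productive, selection-surviving rearrangements, so anchor damage
flows only through the explicit unproductive channel. This is also what
makes the filter pass-rate exactly calibrated to 1 − unproductive_fraction.

Everything is driven by one `numpy` integer-seeded generator: reruns are
bit-identical, and a per-record ground-truth log (V/J choice, CDR3,
mutation and error lists, lesion mode) is sufficient to replay every record,
which a test verifies.

What the simulator does **not** model: nucleotide-level processes (codon
structure, indels, frameshifts), clonal lineage structure, paired
heavy/light chains, isotypes, or realistic germline allele diversity.
Passing tests on synthetic data therefore demonstrate the correctness of
the metric, search, filter and reporting machinery — not biological claims
about real repertoires, whose best-match identity levels depend on
repertoire depth and diversity far beyond desk scale.

## Problem sizes and numerical choices

The test suite exercises search equivalence at 200 queries × 5,000 records
(all three modes, indexed vs exhaustive), metric-oracle equivalence on
1,100 random pairs, and simulator calibration at n = 50,000 (multinomial
3σ bounds on the CDR3 length histogram; binomial 3σ on the filter pass
rate) — sizes at which the checks are sharp while the whole suite stays
fast on a single CPU. Tolerances: identity values are compared exactly (as
rationals) wherever counts are available, and at 1e-12 absolute otherwise;
the only deliberate epsilons are the 1e-9 float-candidate band in the
vectorised argmax (resolved exactly afterwards) and the 1e-12 one-sided
slack in raw-fraction threshold tests.

## Known limitations

* Full-chain search is a linear scan by design; sub-linear search is
  unsound for this metric without approximation, which is out of scope.
* The pairwise-within-set helper is O(n²) and intended for query sets
  (hundreds), not repertoires.
* The FASTA path requires an external numberer; the shipped
  `SequentialNumberer` is a test stub, not an antibody numbering method.
* Positions outside 1–128 are rejected; constant-region spillover must be
  trimmed upstream. Whatever positions are supplied are counted — no
  position-set normalisation across species is attempted.
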