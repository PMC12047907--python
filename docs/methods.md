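# Methods

## Model

`textmol` links a text encoder to an autoregressive chemical language model
through a small trainable adapter, so that conditional molecule generation

    y_t ~ P(y | y_<t, T; θ)

operates in the embedding space of the (frozen) molecule decoder.  The
pieces are:

- **Text encoder.** Word-level token + learned positional embeddings
  followed by bidirectional pre-norm transformer layers (default: 1 layer,
  4 heads, width `d_text`).  Padding positions are excluded from attention
  normalization.  The encoder may be trained jointly with the adapter or
  frozen.
- **Molecule decoder.** A GPT-style causal transformer over molecule tokens
  (SMILES or SELFIES), with a linear language-model head.  It is pretrained
  unconditionally on molecule strings and then frozen; the head is reused
  and frozen too.
- **Adapter.** Single-head cross-attention at the decoder's last layer:
  the text embeddings T are projected to the decoder width (keys and
  values), the molecule token embeddings S act as queries, and softmax is
  taken over text positions, scaled by `1/sqrt(d_mol)` (the scaling is
  toggleable).  The attended value vector enters through a residual
  connection, followed by a pre-norm feed-forward residual block.  Both
  output projections are **zero-initialized**, so an untrained adapter
  reproduces the unconditional decoder's next-token distribution exactly;
  conditioning is a strict delta on the pretrained model and this property
  is tested bit-for-bit.

The published formula for the attention weights is index-inconsistent (its
softmax runs over one index while the update sums over the other against
the wrong vector set); we adopt standard cross-attention with molecule
queries and text keys/values, which matches the stated intent that "the
molecule embedding will be updated" under text guidance.

Default toy widths are `d_mol=128, d_text=96`, 2 decoder layers, 4 heads;
publication-scale settings (256-dimensional, 12 layers, 8 heads) are
expressible through `ModelConfig` but are not exercised by the test suite.
Parameter counts reported by `Module.n_parameters()` are those of this
implementation; they are not calibrated to any published count.

## Training

Teacher forcing with mean cross-entropy over non-pad positions (position i
predicts token i+1).  The optimizer is Adam (β₁=0.9, β₂=0.98, ε=1e-9)
under the Noam schedule

    lr(step) = d_model^-0.5 · min(step^-0.5, step · warmup^-1.5),

linear during warm-up, ∝ step^-0.5 afterwards.  The conventional default
warm-up is 4,000 steps; the desk-scale experiments below shorten both the
run lengths and the warm-up so the schedule peaks inside the run (warm-up
150–300 for runs of 500–700 steps).  Batches are padded to the batch
maximum with loss masking.  Optional early stopping monitors validation
loss with a patience counter; the bundled experiments run a fixed step
count for reproducibility.

Freezing is enforced structurally: frozen tensors are excluded from the
optimizer and the test suite asserts bitwise identity of decoder and head
parameters across optimizer steps.

## Representations

SMILES handling (parsing, validity, canonicalization, fingerprints) is
delegated to RDKit; validity means syntactic parseability plus RDKit's
valence sanity, never a 3D assessment.  SMILES tokenization is
longest-match over a fixed inventory (two-letter elements first, bracket
atoms, ring/branch/bond symbols), since published tokenizers for this task
are not specified.

The SELFIES codec is implemented in-package with the v2-compatible token
spelling and 16-symbol index alphabet.  Decoding follows the robust
derivation semantics: bond orders are capped by remaining valences,
branches and rings that cannot be realized are skipped, and unknown or
end-of-sequence tokens terminate derivation — so *any* stream over the
alphabet decodes to a parseable molecule (property-tested on random
streams), while a stream that derives zero atoms (e.g. EOS first) is
invalid.  Encoding covers kekulizable, single-fragment, non-isotopic
SMILES and drops stereochemistry; every encode verifies its own round trip
and fails loudly rather than silently corrupting.  Valence caps are chosen
to be RDKit-sanitizable (e.g. C⁺ capped at 3), which is deliberately more
conservative than some SELFIES dialects.  Because token spellings differ
across SELFIES dialects, the hard contract is canonical-SMILES round-trip
equality, not token-string equality; the printed reference SELFIES of
4-methylphenol is required to *decode* to the reference molecule.

## Dataset curation

Fixed order, each stage with a logged count: validity → strict word-count
filter (whitespace-delimited, strictly greater-than the threshold; 20 and
30 are the conventional settings) → exact-duplicate collapse (description +
canonical molecule) → one-to-many removal (a description mapped to more
than one distinct canonical SMILES loses all its rows; several
descriptions of one molecule are kept) → overlap removal against a
reference table by canonical SMILES.  The curation order is this package's
own choice; published descriptions of such pipelines list the filters but
not an order.  Any further source-specific filters beyond these are out of
scope, and the JSON curation report makes the implemented set explicit.

## Generation

Sampling is greedy (argmax, ties to the lowest index) or multinomial on
`softmax(logits/temperature)`; the conventional sampling seed default is
42.  The escalation protocol draws one sample at temperature 1.0, then
escalates from 1.5 in increments of 0.5 (the published protocol reports the
1.5 start, the 1,000-samples-per-temperature cap and the 4.5 ceiling but
not the step size; 0.5 is configurable) until the target number of
filter-passing unique molecules is collected.  Seeds are `base + draw
index`, logged per sample.  Deduplication is global across temperatures by
canonical SMILES and applies to every parseable sample; unparseable strings
are never duplicates and always consume a logged iteration.  Exhausting the
ceiling yields a partial log with an explicit shortfall flag.

## Evaluation

Exact match is canonical-SMILES equality.  Fingerprint Tanimoto
similarities use MACCS keys (166 bits), RDKit path fingerprints (defaults),
and Morgan radius 2 / 2048 bits — the parameter conventions of the MolT5
evaluation lineage, since the metric descriptions name the fingerprints but
not their parameters.  Means are over valid generated molecules only;
empty∩empty fingerprint pairs score 1.0 with a warning.  The four
post-generation filters: natural-language (whitespace or spans outside the
molecular alphabet), invalid (unparseable), salt (more than one
'.'-separated fragment; keeping only the largest fragment would change the
string, which fails the unchanged-after-filtering rule), single-element
(all heavy atoms share one element, hydrogens ignored — so plain alkanes
are flagged; the published rule is informal and this reading is strict).
Campaign statistics: unique = samples − duplicates; success rate = 100 ·
successes / unique, one decimal.  Exponential consensus ranking uses the
standard form `score = Σ (1/σ)·exp(−rank/σ)` with a single σ for all
scorers, default 5% of the list length.

## Synthetic data

The generator emulates paired molecule-description data in which the text
deterministically encodes four checkable structural properties: heavy-atom
count (3–9), ring presence, oxygen content, halogen content.  Molecules
come from an enumerated template family — carbon chains, saturated 5/6
rings, benzene cores, hydroxyl tails, F/Cl substituents — so
`check_property` is exact graph inspection.  Descriptions are templated
(>20 words, satisfying the curation rule by construction) with two
distractor clauses and a unique registry-identifier clause; the identifier
keeps every row's text unique so generated tables pass curation with zero
drops, and the distractors force the encoder to select the informative
clauses.  What this does *not* emulate: real ontology-style text,
functional/bioactivity language, large vocabularies, ambiguous or
many-to-many pairings, and molecules beyond a few heavy atoms — so passing
tests demonstrate that the architecture can condition on text, not that it
reaches publication-scale similarity numbers on real corpora.

## Conditioning surrogate (study conditions)

`run_conditioning_experiment`: 2,000 training pairs, 200 held-out specs,
SELFIES targets, toy widths (`d_mol=64, d_text=48`, 2 decoder layers, 4
heads, 1 text layer); decoder pretraining 500 steps (batch 64, warm-up
150), adapter training 700 steps (batch 48, warm-up 200); evaluation draws
one multinomial sample (temperature 1.0) per held-out description and the
same number of unconditional samples.  These problem sizes are the
package's desk-scale study conditions, chosen once so a full run finishes
in minutes on one CPU.  The acceptance test requires the conditional
property-match rate to exceed the unconditional baseline by ≥ 20 points on
each of three seeds; observed runs sit near 0.85–0.92 conditional vs
0.03–0.04 unconditional.

## Numerical choices and edge cases

- All tensors are float64; attention masking adds −1e9 to excluded scores;
  softmax subtracts a detached rowwise maximum.
- Greedy ties break to the lowest index; `temperature > 0` is enforced.
- Cross-entropy with an all-zero mask, empty tables, empty pair lists,
  fraction vectors that do not sum to 1, step 0 of the Noam schedule, and
  non-finite losses all raise immediately with diagnostic messages.
- Sampling in a batch gives each row its own RNG stream (seed + row), so
  batched and one-at-a-time generation produce identical strings.
- The zero-atom decode ('' from a SELFIES stream) is reported as invalid,
  matching the EOS-at-the-beginning failure mode of SELFIES-based models.

## Known limitations

- The SELFIES encoder rejects isotopes, disconnected fragments, and a few
  exotic bracket atoms; stereochemistry is dropped in conversion (it is
  preserved by canonicalization unless the strip-stereo switch is used).
- The decoder is a desk-scale stand-in trained on the synthetic grammar;
  no pretrained checkpoints are loaded, and published similarity tables
  for real corpora are out of reach by design.
- Docking, 3D conformer generation, and efflux-ratio prediction are out of
  scope; consensus ranking is provided as the generic aggregation step
  only.
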