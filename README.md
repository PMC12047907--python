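# textmol

Text-conditioned molecule generation by *linking* two single-domain models:
a natural-language encoder and an autoregressive chemical language model
(a GPT-style decoder over SMILES or SELFIES strings), joined by a small
cross-attention adapter at the decoder's last layer.  The decoder and its
language-model head stay frozen; only the adapter (and optionally the text
encoder) is trained, so conditional generation

    y_t ~ P(y | y_<t, T; θ)

is obtained while remaining inside the pretrained molecule model's
embedding space.  The adapter projects the text embeddings T = {t₁…t_m} to
the decoder width, attends from the molecule token embeddings S = {s₁…s_n}
(queries) to the projected text (keys/values) with softmax over text
positions, and feeds the updated embeddings to the decoder's own LM head.
Both adapter output projections are zero-initialized, so before training
the conditional model is *exactly* the unconditional decoder.

The package is aimed at people studying this adapter-linking recipe at
desk scale: it ships the full surrounding machinery — dataset curation for
paired description/molecule tables, SMILES/SELFIES handling with a robust
SELFIES codec, teacher-forcing training under the Noam schedule,
temperature-escalation sampling, fingerprint-similarity evaluation,
post-generation filters with campaign statistics, and exponential
consensus ranking — plus a seeded synthetic-data generator whose
descriptions deterministically encode checkable structural properties, so
conditioning quality is measurable without downloading any corpus.

## Worked example

```bash
# 1. a synthetic paired table (descriptions encode structural properties)
textmol synth --n 2000 --seed 1 --out pairs.tsv

# 2. curation (word-count rule, dedup, one-to-many, overlap) with a report
textmol curate --in pairs.tsv --out curated.tsv --report report.json

# 3. pretrain the decoder on the table's molecules, then train the adapter
textmol train --pairs curated.tsv --outdir model/ --seed 1

# 4. generate one molecule per description and score against references
textmol generate --model-dir model/ --table curated.tsv --out gen.txt --seed 42
textmol evaluate --pairs curated.tsv --generations gen.txt \
    --repr-kind selfies --out-json metrics.json
```

The same pipeline through the Python API, with the numbers it prints:

```python
>>> from textmol.synthetic import run_conditioning_experiment
>>> result = run_conditioning_experiment(seed=1)
>>> result["conditional_match_rate"], result["unconditional_match_rate"]
(0.88, 0.035)
```

Here 0.88 is the fraction of held-out descriptions whose sampled molecule
satisfies every property stated in the text (heavy-atom count, ring,
oxygen, halogen), against 0.035 for the unconditional decoder on the same
specifications — the adapter lifts property adherence by ~85 points under
these study conditions.  Example rows of the synthetic table:

```
SYN000000  CCCCCCCCl  "... The molecule contains a total of 8 heavy atoms.
                       It is acyclic with no ring system. ..."
SYN000001  CCCCO      "... The molecule contains a total of 5 heavy atoms. ..."
```

String handling example — 4-methylphenol:

```python
>>> from textmol.chem import smiles_to_selfies, selfies_to_smiles
>>> smiles_to_selfies("Cc1ccc(O)cc1")
'[C][C][=C][C][=C][Branch1][C][O][C][=C][Ring1][#Branch1]'
>>> selfies_to_smiles(_)
'CC1=CC=C(O)C=C1'
```

Campaign statistics (the Table-style success-rate row):

```python
>>> from textmol.generation import GenerationLog
>>> from textmol.evaluation import generation_stats
>>> generation_stats(GenerationLog.from_counts(260, 31, 113, 8, 4, 4)).success_rate
43.7
```

i.e. 260 samples minus 31 duplicates leaves 229 unique molecules, of which
100 pass all four filters: 100/229 = 43.7%.

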