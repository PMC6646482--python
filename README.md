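# radmeasure

Extraction of lesion measurements and their descriptors from free-text
radiology reports.

Radiology reports record lesion sizes — the key quantitative signal for
tracking tumor burden across encounters — as free narrative text ("4 mm left
frontal nodule (image 127, previously 7 mm)"). `radmeasure` turns each such
size expression into one structured **frame**: the measurement (1–3
dimensions, value + unit) plus seven descriptors that make it uniquely
identifiable for lesion tracking:

1. **temporality** — does the size describe the current scan (`CURRENT`) or
   quote an earlier study (`PRIOR`)?
2. **anatomical entity** — body structure / laterality ("left frontal", "liver")
3. **imaging observation** — the finding being measured ("nodule", "mass")
4. **RadLex descriptor** — qualifiers of the finding ("scattered", "cystic")
5. **image number**, 6. **series number** — where the measurement was made
7. **segment** — numbered organ subdivision (e.g. hepatic segment 5)

It is a hybrid system: regular-expression grammars tag measurements,
temporality cues and image/series/segment references; a sentence containing
several measurements is divided into *sub-sentences* (one measurement each)
that scope descriptor linking; entities are tagged either by a dictionary
baseline (greedy leftmost-longest lexicon lookup) or by a trainable
linear-chain **CRF** over token features (lowercased form, POS tag,
dictionary-map flags, affixes, digit flag, ±2 context window — no chunk or
parse features); rules then link everything into frames. An evaluator scores
frames per information type (precision/recall/F) and per measurement
(full / partial / no match), and a seeded synthetic-report generator provides
gold-annotated corpora so the whole system trains and tests without any
clinical data.

## Worked example

```python
from radmeasure import build_frames, load_lexicons, serialize_frames
import sys

report = """CLINICAL HISTORY: Follow-up of known malignancy.
FINDINGS: Right lower lobe nodule measures 4 mm (image 38, series 2), \
previously 7 mm. There is a scattered ground-glass opacity in the left \
upper lobe measuring 1.2 x 0.8 cm.
IMPRESSION: Overall decreased disease burden.
"""
frames = build_frames(report, load_lexicons(), doc_id="case-001")
serialize_frames(frames, sys.stdout)
```

prints three frames (abridged):

```json
{"frame_id": "case-001:0:0", "surface": "4 mm",  "temporality": "CURRENT",
 "anatomical_entity": ["Right lower lobe"], "imaging_observation": ["nodule"],
 "image_number": 38, "series_number": 2}
{"frame_id": "case-001:0:1", "surface": "7 mm",  "temporality": "PRIOR",
 "anatomical_entity": ["Right lower lobe"], "imaging_observation": ["nodule"]}
{"frame_id": "case-001:1:0", "surface": "1.2 x 0.8 cm", "temporality": "CURRENT",
 "anatomical_entity": ["left upper lobe"],
 "imaging_observation": ["ground-glass opacity"], "radlex_descriptor": ["scattered"]}
```

The first Findings sentence yields two frames: the current 4 mm size with its
image/series location, and the quoted prior 7 mm size, which inherits the
anatomy and observation of its current counterpart but is labeled `PRIOR`.
The second sentence shows a two-dimension measurement with its modifier
chain.

## Command line

```bash
radmeasure synth   --out corpus/ --seed 7 --n-reports 100   # synthetic gold corpus
radmeasure train   --corpus corpus/standoff.jsonl --out model.json
radmeasure extract corpus/manifest.json --mode crf --model model.json --out frames.jsonl
radmeasure eval    --system frames.jsonl --gold corpus/gold_frames.jsonl \
                   --metrics-out metrics.csv --matches-out matches.csv
```

`extract` defaults to the dictionary baseline (`--mode baseline`); `eval`
writes a per-information-type metrics table and a descriptor-combination
match table, and prints the full/partial/no-match counts.

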