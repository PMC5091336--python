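# Methods

## Task and model

The recognizer labels every *sub-token* of a sentence with one of 13
labels: `O` or a SOBIE tag (`S`ingleton, `B`egin, `I`nside, `E`nd)
crossed with a composed chemical class (`Chem`, `Struct`, `Atom`).
Mentions are recovered from label runs and reported as character-offset
spans; the title (`T`) and abstract (`A`) of a document are independent
offset spaces, 0-based and end-exclusive, counted in Unicode code points
(the corpus layout itself does not fix a convention; code points make the
substring invariant `text == passage[start:end]` trivial to enforce, and
every load enforces it).

The sequence model is a linear-chain conditional random field

  p(y | x) ∝ exp( Σ_t [ w·f(x, t, y_t) + A_{y_{t-1}, y_t} ] + s_{y_1} + e_{y_T} )

with binary observation features f, a 13×13 transition matrix A and
start/end potentials. Training maximizes the exact conditional
log-likelihood with an L2 penalty `c2·‖θ‖²` using L-BFGS; prediction is
the Viterbi path. Prediction confidence (written as the 7th column of
prediction files) is the mean posterior marginal of the predicted path's
labels.

### Class composition and the Atom class

Raw class → composed class: IDENTIFIER, FAMILY, TRIVIAL, ABBREVIATION →
`Chem`; SYSTEMATIC, FORMULA, MULTIPLE → `Struct`. `Atom` is derived, not
annotated: a FORMULA mention whose aligned token range is a single full
token of at most 3 characters, and whose every alphanumeric sub-token is
one of the 118 element symbols optionally followed by digits (`Cu`,
`H2`), trains as `Atom`. The rule is a construction of this package (the
class's purpose — sharpening formula recognition on bare element symbols
— constrains but does not determine it); the length-3 cut keeps
multi-element strings like `C9H8O4` in `Struct`. Contiguous runs of
predicted Atom singletons merge into one formula mention
(`decode_sobie(..., merge_atom_runs=False)` emits per-atom mentions
instead). On output the internal ATOM class maps back to FORMULA, so the
system's prediction files contain only corpus classes; decoded `Chem` and
`Struct` mentions are written with representative raw classes (TRIVIAL,
SYSTEMATIC) because the file format carries raw-class tokens while
span-level CEMP scoring ignores them.

### Label codec

Encoding: a mention covering one sub-token gets `S-cls`; longer mentions
get `B`, interior `I`s (including punctuation sub-tokens inside the
span) and `E`. Mention boundaries that cut a sub-token snap outward with
a logged warning. Overlapping gold mentions (rare annotation artifacts)
are resolved longest-first, ties leftmost, before encoding. Decoding
treats well-formed spans exactly — so decode∘encode is the identity on
aligned, non-overlapping mention sets — and repairs ill-formed output
permissively: an orphan `I`/`E` opens a new mention, a missing `E` closes
at the last token of the run. Permissive repair favours recall.

## Tokenization

Three aligned granularities:

* **words** — whitespace-delimited spans;
* **full tokens** — words with sentence punctuation (`, . ; : ! ? " ' (
  )`) detached at the edges only; internal hyphens and brackets stay, so
  `9-hydroxy-pyrido[1,2-a]pyrimidin-4-one` is one full token;
* **sub-tokens** — full tokens split at every character of
  `- – , . ; : ( ) [ ] { } = / \ ' " +`; each delimiter is its own
  punctuation sub-token, and concatenating a token's sub-tokens
  reproduces it exactly (property-tested).

Sentence boundaries are `.`/`!`/`?` followed by whitespace and an
uppercase letter or digit, guarded by an abbreviation list (`e.g.`,
`Fig.`, …) and by single-letter words (initials, element symbols).
Sentence spans tile the passage so all offsets stay global.
Letter↔digit transitions do **not** split sub-tokens — the delimiter set
is punctuation only, which keeps `C9H8O4` a single sub-token; this is a
deliberate reading, and digit-transition splitting was left out rather
than made configurable because nothing downstream exercises it.

Each sub-token maps to its enclosing whitespace-delimited word for the
full-token features; punctuation sub-tokens map to themselves, so
delimiters never inherit the surface features of the expression around
them. (An alternative reading would also map affix-like fragments to
themselves; the simpler punctuation-only rule is implemented.)

## Features

Feature groups, toggled per training run:

* `baseline` — digit-normalized word (every digit → `1`, so `C9H8O4` →
  `C1H1O1`); POS tag; prefixes/suffixes of lengths 1–4 (digit-normalized);
  orthographic flags (InitCap, AllCaps, HasDigit, AllDigit, IsPunct,
  HasGreek); word shape raw and run-collapsed (`Aspirin` → `Xx`); the
  digit-normalized words of neighbours at offsets −2…+2 with
  `__BOS__`/`__EOS__` sentinels. Affix lengths 1–4 and window ±2 are
  conventional CRF-NER choices.
* `bioNE` — `O` or `B-`/`I-` + {DNA, RNA, protein, cell_line, cell_type}
  from a pluggable annotator. The default is a gazetteer maximum-matcher
  over the built-in decoy vocabulary; pre-computed spans can be supplied
  as a 5-column sidecar file. A provider failure degrades to all-`O` with
  a warning.
* `dictionary` — three values per sub-token: membership in the CTD-style
  chemical gazetteer, the drug gazetteer, and their union, each encoded
  `O`/`B-type`/`I-type` (B/I adds span information at no cost over a bare
  type value). Matching is greedy longest-match left-to-right over
  *words*, case-insensitive, with edge punctuation stripped from query
  words; verified against a brute-force enumeration oracle.
* `fulltoken_ortho` — five regexes evaluated on the enclosing word:
  `\[.*?\]`, `\(.*?\)`, `\S+,\S+`, `\d,\d`, `\d-\d` (non-greedy, searched
  anywhere in the word, exactly as specified).
* `fulltoken_boundary` — `B` if the sub-token begins its full token,
  else `I`.

Feature extraction is pure: identical sentence and resources give
identical rows. The POS tagger is a built-in deterministic suffix-rule
tagger (closed-class lookup, suffix rules, digit/punctuation classes); it
is a coarse shape signal, not linguistic analysis, and is pluggable.

## CRF engine numerics

The engine is implemented in-package on numpy/scipy. Observation
features are label-independent strings; the design matrix is a sparse
CSR indicator matrix over all tokens, so per-iteration emission scores
and gradients are two sparse matrix products. Forward–backward runs in
log space, vectorized across all sequences at once: sequences are sorted
longest-first and padded, and each time step updates only the prefix of
still-active sequences; the backward recursion is fused with the
pairwise-marginal accumulation so the tensor `A + E_{t+1} + β_{t+1}` is
built once. Gradients were verified against central finite differences.

Defaults: `c2 = 1.0`, `max_iterations = 200` (L-BFGS usually converges
earlier on the synthetic corpora). The optimization is seed-free and
starts from zero weights, so training is bit-deterministic; the
`random_seed` field is recorded in the model header for provenance.
Model files are JSON containers (format tag, version, toggle set, label
alphabet, weights); the feature vocabulary is stored in first-seen order,
which makes serialized models byte-identical across reruns.

## Refinement

After tagging, the distinct predicted surface strings of a document —
excluding Atom-derived mentions — are re-scanned over both passages with
greedy leftmost-longest maximum matching. Matches must start and end on
sub-token boundaries (so `Ag` cannot fire inside `Agent`) and are
case-sensitive by default (`Co` vs `CO`); a flag relaxes case. A string
predicted with conflicting classes takes its majority class, ties →
`Chem`. Candidates overlapping any existing prediction are discarded:
refinement is add-only and can only raise recall. Only document-internal
strings are used (the external dictionaries are features, not refinement
sources). The scan is verified against a brute-force oracle.

## Evaluation

CEMP: exact-span, one-to-one matching per document — a prediction is a
true positive iff an unconsumed gold mention has the identical (passage,
start, end); duplicates of one gold span yield 1 TP + 1 FP. Counts are
pooled over all documents before rates (micro-averaging). Class-blind by
default, since the task scores a single merged chemical type; a
class-sensitive mode compares composed classes. Percentages are reported
to 3 decimals.

CPD: each title and each abstract is one binary instance, positive iff
it contains ≥1 mention; sensitivity, specificity, accuracy (percent) and
MCC (in [−1, 1]; degenerate denominators → 0). `rate_consistency`
inverts a (sens, spec, acc) triple into the implied positive fraction
p = (acc − spec)/(sens − spec) and normalized confusion matrix, which
lets reported metric triples be checked against each other and their MCC
recomputed.

## Synthetic corpus

The generator emulates the corpus *layout and class inventory*, not
patent language. Each document is a 1-sentence title and a 2–3-sentence
abstract of template carrier text; mention counts per document are
Poisson (mean 3.0, so ~5% of documents are chemical-free and CPD has
negatives); each mention lands in the title with probability 0.25. The
default class mixture (SYSTEMATIC .30, TRIVIAL .22, FAMILY .15,
ABBREVIATION .12, FORMULA .10, IDENTIFIER .08, MULTIPLE .03) is weighted
toward systematic and trivial names as in medicinal-chemistry patent
text. Surface strings come from class-specific grammars: locant/fragment
grammars with brackets for SYSTEMATIC, element-count and bond strings
for FORMULA (25% bare element symbols to exercise the Atom class),
letter+digit codes for IDENTIFIER, enumerations for MULTIPLE, and closed
word lists for TRIVIAL/FAMILY/ABBREVIATION. 30% of sentences carry an
unannotated biological decoy (protein/cell-line/nucleic-acid names, many
of them chemical-looking codes like `MCF7`), which makes precision
non-trivial and gives the Bio-NE feature something to discriminate. The
built-in CTD/drug gazetteers are derived from the same vocabulary and
are explicitly synthetic stand-ins for the licensed resources.

What passing on this corpus does **not** show: robustness to real patent
syntax, unseen trivial-name vocabulary, composite mentions
(`(C1-C4) alkoxy methyl`), nested or discontinuous mentions, or
statistical fidelity of any kind. The corpus is deliberately learnable —
its grammars are regular and its vocabularies closed — so end-to-end
scores here are a pipeline-correctness bar (median F ≥ 90% across seeds),
not a benchmark claim.

## Problem sizes

The learnability experiment trains on 500 documents and evaluates on 100
held-out documents from the same generator configuration, over 5
replicate seeds, with refinement on; the feature-ablation series
(baseline → +bioNE → +fulltoken_ortho → +fulltoken_boundary) runs at a
reduced 120/50-document scale with 3 seeds and 100 optimizer iterations,
which is ample for the stability question it answers. The acceptance
script reports the median-F replicate's metrics at the 500/100 scale.

## Known limitations

* The CRF hyperparameters are common-practice defaults, not tuned to any
  external benchmark; results on real corpora would need the real
  GENIA-style annotators and licensed dictionaries behind the same
  provider interfaces.
* The rule-based sentence splitter and POS tagger are deliberately
  simple; both are pluggable seams.
* One CRF covers all three composed classes; per-class recognizers are
  out of scope.
* Published corpus-level figures for some development-set runs are not
  internally harmonic-consistent (printed F ≠ harmonic mean of printed
  P/R); only the test-set tables' arithmetic is treated as
  self-consistent and asserted in tests.
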