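"""Synthetic patent-abstract corpora with planted chemical mentions.

Documents are template sentences in patent-abstract register, with
mentions of all seven corpus classes generated from class-specific
grammars that imitate their naming conventions (systematic names with
locants/brackets, element-count formulae, letter-digit identifiers,
closed lists of trivial/family/abbreviation names, comma enumerations).
Biological decoy entities (protein, cell-line and nucleic-acid names,
many of them chemical-looking letter-digit codes) are planted unannotated
so precision is not trivially 100%.

Gold offsets are exact by construction, sentences are period-delimited,
and mentions never straddle sentence boundaries. Identical configuration
and seed reproduce byte-identical corpora. Carrier text is synthetic — it
exercises the pipeline, it does not emulate real patent language.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field
from pathlib import Path

from nerchem.corpus_io import Document, Mention, write_annotations, write_documents
from nerchem.features import DictionaryResource, GazetteerBioNEProvider

RAW_CLASSES = (
    "ABBREVIATION",
    "FAMILY",
    "FORMULA",
    "IDENTIFIER",
    "MULTIPLE",
    "SYSTEMATIC",
    "TRIVIAL",
)

#: Default class mixture, weighted toward systematic and trivial names as
#: in medicinal-chemistry patent text.
DEFAULT_CLASS_MIX = {
    "SYSTEMATIC": 0.30,
    "TRIVIAL": 0.22,
    "FAMILY": 0.15,
    "ABBREVIATION": 0.12,
    "FORMULA": 0.10,
    "IDENTIFIER": 0.08,
    "MULTIPLE": 0.03,
}

TRIVIAL_NAMES = (
    "aspirin menthol azithromycin caffeine ibuprofen morphine nicotine "
    "paracetamol penicillin quinine glucose sucrose ethanol acetone benzene "
    "toluene urea cholesterol dopamine serotonin camphor limonene vanillin "
    "thymol eugenol geraniol citral naproxen warfarin atropine"
).split()

FAMILY_NAMES = (
    "halogen alkaloid flavonoid terpene steroid opioid barbiturate "
    "benzodiazepine sulfonamide quinolone polyphenol carotenoid anthocyanin "
    "prostaglandin spiromethylene phenothiazine macrolide"
).split()

ABBREV_NAMES = (
    "DMSO THF DMF ATP EDTA GABA PEG TNT PVC NAD DDT BPA MTBE TCA DMA"
).split()

#: Subset of trivial names treated as the drug gazetteer.
DRUG_NAMES = (
    "aspirin ibuprofen morphine azithromycin paracetamol penicillin quinine "
    "naproxen warfarin atropine"
).split()

#: Biological decoy entities, keyed by Bio-NE type. Many are letter-digit
#: codes shaped like chemical identifiers.
BIO_DECOYS = {
    "protein": ["p53", "EGFR", "BRCA1", "TNF", "AKT1", "STAT3", "kinase"],
    "cell_line": ["HeLa", "MCF7", "HEK293", "CHO", "A549"],
    "cell_type": ["fibroblast", "lymphocyte", "hepatocyte", "macrophage"],
    "DNA": ["cDNA", "plasmid"],
    "RNA": ["mRNA", "siRNA"],
}

_CARRIER = (
    "the present invention relates to a composition method for treatment of "
    "preparing comprising derivative novel effective agent process mixture "
    "solution therapeutic activity against disorders use thereof provides "
    "described wherein said pharmaceutical acceptable carrier dose patients "
    "inhibiting expression levels in cells tested obtained improved stable"
).split()

_STARTERS = "The A Novel Said This Disclosed Provided".split()

_SYS_FRAGMENTS = (
    "methyl ethyl propyl butyl phenyl chloro fluoro bromo hydroxy amino "
    "nitro oxo methoxy ethoxy cyclohexyl benzyl acetyl hydroxymethyl "
    "fluorocytosin"
).split()
_SYS_CORES = (
    "oxathiolane pyrimidin pyridine imidazole oxazole thiazole furan pyran "
    "indole quinoline pyrazole benzamide"
).split()
_SYS_SUFFIXES = "one ol amine oxide dione".split()

_FORMULA_ELEMENTS = "C H N O S Cl Na K P F Br".split()
_ATOM_SYMBOLS = "H Cu Ag Fe Zn Mg Ca Au Pt Ni".split()
_BOND_UNITS = "CH CH2 NH O S".split()


@dataclass(frozen=True)
class GeneratorConfig:
    """Conditions under which a synthetic corpus is produced."""

    n_documents: int = 100
    mentions_per_doc: float = 3.0  # Poisson mean
    class_mix: dict = field(default_factory=lambda: dict(DEFAULT_CLASS_MIX))
    random_seed: int = 0
    carrier_vocab_size: int = 40
    decoy_rate: float = 0.3  # probability a sentence carries a bio decoy

    def __post_init__(self) -> None:
        if self.n_documents < 1:
            raise ValueError("n_documents must be >= 1")
        total = sum(self.class_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"class_mix must sum to 1, got {total}")
        if set(self.class_mix) - set(RAW_CLASSES):
            raise ValueError("class_mix contains unknown classes")


# ---------------------------------------------------------------------------
# Mention grammars


def generate_mention(cls: str, rng: random.Random) -> str:
    """One surface string of the given raw class."""
    if cls == "TRIVIAL":
        return rng.choice(TRIVIAL_NAMES)
    if cls == "FAMILY":
        return rng.choice(FAMILY_NAMES)
    if cls == "ABBREVIATION":
        return rng.choice(ABBREV_NAMES)
    if cls == "IDENTIFIER":
        letters = "".join(rng.choice("ABCDEFGHJKLMNPQRSTVWXYZ") for _ in range(rng.randint(2, 4)))
        digits = "".join(rng.choice("0123456789") for _ in range(rng.randint(3, 4)))
        return letters + digits
    if cls == "FORMULA":
        return _generate_formula(rng)
    if cls == "SYSTEMATIC":
        return _generate_systematic(rng)
    if cls == "MULTIPLE":
        return _generate_multiple(rng)
    raise ValueError(f"unknown raw class {cls!r}")


def _generate_formula(rng: random.Random) -> str:
    kind = rng.random()
    if kind < 0.25:  # bare atom, the Atom-class trainer
        sym = rng.choice(_ATOM_SYMBOLS)
        return sym + (rng.choice("23") if rng.random() < 0.3 and len(sym) == 1 else "")
    if kind < 0.75:  # element-count string like C9H8O4
        k = rng.randint(2, 4)
        elements = rng.sample(_FORMULA_ELEMENTS, k)
        parts = []
        for el in elements:
            count = rng.randint(1, 12)
            parts.append(el + (str(count) if count > 1 else ""))
        return "".join(parts)
    # bond string like -CH=CH-CH=CH-
    units = [rng.choice(_BOND_UNITS) for _ in range(rng.randint(2, 4))]
    return "-" + "-".join("=".join([u, rng.choice(_BOND_UNITS)]) for u in units) + "-"


def _generate_systematic(rng: random.Random) -> str:
    segments = []
    for _ in range(rng.randint(1, 3)):
        locant = str(rng.randint(1, 9))
        if rng.random() < 0.3:
            locant = f"{rng.randint(1, 5)},{rng.randint(2, 9)}"
        segments.append(f"{locant}-{rng.choice(_SYS_FRAGMENTS)}")
    if rng.random() < 0.4:
        inner = f"{rng.randint(1, 9)}-{rng.choice(_SYS_FRAGMENTS)}-{rng.randint(1, 4)}-yl"
        segments.append(f"{rng.randint(1, 9)}-({inner})")
    core = rng.choice(_SYS_CORES)
    if rng.random() < 0.35:
        core += f"[{rng.randint(1, 3)},{rng.randint(1, 3)}-a]{rng.choice(_SYS_CORES)}"
    tail = f"-{rng.randint(1, 6)}-{rng.choice(_SYS_SUFFIXES)}" if rng.random() < 0.5 else ""
    return "-".join(segments) + "-" + core + tail


def _generate_multiple(rng: random.Random) -> str:
    if rng.random() < 0.5:
        letter = rng.choice("BDE")
        return f"vitamin {letter}-{rng.randint(1, 9)}, {letter}{rng.randint(10, 12)}"
    base = rng.choice(TRIVIAL_NAMES).capitalize()
    letters = rng.sample("ABCDE", rng.randint(2, 3))
    return f"{base} {','.join(letters)}"


# ---------------------------------------------------------------------------
# Document assembly


def _poisson(rng: random.Random, lam: float) -> int:
    # Knuth's method; lam is small here
    import math

    limit = math.exp(-lam)
    k, p = 0, 1.0
    while True:
        p *= rng.random()
        if p <= limit:
            return k
        k += 1


def _build_sentence(
    rng: random.Random,
    mentions: list[tuple[str, str]],  # (surface text, raw class)
    carrier: list[str],
    decoy: str | None,
) -> tuple[str, list[tuple[int, int, str, str]]]:
    """One sentence; returns (text, [(start, end, text, raw class)])."""
    n_carrier = rng.randint(4, 8)
    words: list[tuple[str, str | None]] = [(rng.choice(_STARTERS), None)]
    words += [(rng.choice(carrier), None) for _ in range(n_carrier)]
    if decoy:
        words.insert(rng.randint(1, len(words)), (decoy, None))
    for text, cls in mentions:
        words.insert(rng.randint(1, len(words)), (text, cls))
    pieces = []
    spans = []
    pos = 0
    for i, (w, cls) in enumerate(words):
        if i:
            pieces.append(" ")
            pos += 1
        if cls is not None:
            spans.append((pos, pos + len(w), w, cls))
        pieces.append(w)
        pos += len(w)
    pieces.append(".")
    return "".join(pieces), spans


def _build_passage(
    rng: random.Random,
    passage: str,
    n_sentences: int,
    mention_classes: list[str],
    cfg: GeneratorConfig,
    carrier: list[str],
) -> tuple[str, list[Mention]]:
    per_sentence: list[list[str]] = [[] for _ in range(n_sentences)]
    for cls in mention_classes:
        per_sentence[rng.randrange(n_sentences)].append(cls)
    text_parts: list[str] = []
    mentions: list[Mention] = []
    offset = 0
    for si in range(n_sentences):
        decoy = None
        if rng.random() < cfg.decoy_rate:
            ne_type = rng.choice(sorted(BIO_DECOYS))
            decoy = rng.choice(BIO_DECOYS[ne_type])
        pairs = [(generate_mention(c, rng), c) for c in per_sentence[si]]
        sent, spans = _build_sentence(rng, pairs, carrier, decoy)
        if si:
            text_parts.append(" ")
            offset += 1
        for s, e, t, cls in spans:
            mentions.append(
                Mention(passage=passage, start=offset + s, end=offset + e, text=t, raw_class=cls)
            )
        text_parts.append(sent)
        offset += len(sent)
    return "".join(text_parts), mentions


def _sample_class(rng: random.Random, mix: dict[str, float]) -> str:
    r = rng.random()
    acc = 0.0
    for cls in RAW_CLASSES:  # fixed iteration order for determinism
        acc += mix.get(cls, 0.0)
        if r < acc:
            return cls
    return RAW_CLASSES[-1]


def generate_documents(cfg: GeneratorConfig = GeneratorConfig()) -> list[Document]:
    """The synthetic corpus as in-memory documents with gold mentions."""
    rng = random.Random(cfg.random_seed)
    carrier = _CARRIER[: cfg.carrier_vocab_size]
    docs = []
    for i in range(cfg.n_documents):
        doc_id = f"SYN{cfg.random_seed:04d}{i:05d}"
        n_mentions = _poisson(rng, cfg.mentions_per_doc)
        classes = [_sample_class(rng, cfg.class_mix) for _ in range(n_mentions)]
        # each mention lands in the title with probability 0.25
        title_classes, rest = [], []
        for c in classes:
            (title_classes if rng.random() < 0.25 else rest).append(c)
        title, t_mentions = _build_passage(rng, "T", 1, title_classes, cfg, carrier)
        abstract, a_mentions = _build_passage(
            rng, "A", rng.randint(2, 3), rest, cfg, carrier
        )
        docs.append(
            Document(
                doc_id=doc_id,
                title=title,
                abstract=abstract,
                gold_mentions=t_mentions + a_mentions,
            )
        )
    return docs


def generate_corpus(
    cfg: GeneratorConfig, out_prefix: str | Path
) -> tuple[Path, Path]:
    """Write ``<prefix>.docs.tsv`` and ``<prefix>.ann.tsv``; returns paths."""
    docs = generate_documents(cfg)
    prefix = Path(out_prefix)
    docs_path = Path(f"{prefix}.docs.tsv")
    ann_path = Path(f"{prefix}.ann.tsv")
    write_documents(docs, docs_path)
    write_annotations(docs, ann_path)
    return docs_path, ann_path


# ---------------------------------------------------------------------------
# Default resources matched to the generator's vocabulary


def default_dictionaries() -> list[DictionaryResource]:
    """CTD-chemical and DrugBank-style gazetteers over the generator's
    chemical vocabulary (stand-ins for the real licensed dictionaries)."""
    ctd = DictionaryResource("CTD_CHEM", set(TRIVIAL_NAMES) | set(FAMILY_NAMES) | set(ABBREV_NAMES))
    drug = DictionaryResource("DRUG", set(DRUG_NAMES))
    return [ctd, drug]


def default_bione_gazetteer() -> GazetteerBioNEProvider:
    return GazetteerBioNEProvider({k: list(v) for k, v in BIO_DECOYS.items()})
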