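"""Descriptive statistics of sonographer speech during scanning.

Sonographers narrate scans in a small, highly stereotyped vocabulary (on
the order of a few hundred unique words).  This module computes token-level
part-of-speech (POS) fractions, vocabulary size and maximum sentence length
over a transcript corpus.  Tagging is purely lexicon-based: every word maps
to one of five coarse tags (adjective, determiner, noun, verb, other) via a
word -> tag table, with no statistical tagger involved — the corpus must be
covered by the lexicon, and out-of-lexicon words are reported as errors
rather than silently skipped.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .reference import POS_TAGS

_WORD_RE = re.compile(r"[a-z0-9']+")

# Default tagged lexicon: a plausible working vocabulary for narrated
# obstetric scanning, grouped by coarse POS tag.  Each word carries exactly
# one tag (homographs are assigned their dominant scanning-speech use).
_DETERMINERS = (
    "the a an this that these those some any each every another all both".split()
)
_ADJECTIVES = (
    "good nice clear normal abnormal small little big large long short left "
    "right upper lower anterior posterior fetal maternal cardiac abdominal "
    "cephalic breech transverse sagittal coronal axial open closed full empty "
    "high low visible difficult easy happy wriggly active quiet still perfect "
    "lovely tricky deep shallow bright dark fuzzy sharp round curved straight "
    "top bottom middle best better early late ready comfy".split()
)
_VERBS = (
    "is are was were be been being see look looking looked check checking "
    "measure measuring measured move moving moved turn turning freeze frozen "
    "save saving scanning find found show showing shows try trying get "
    "getting go going gone come coming take taking took press pressing "
    "breathe relax lie hold holding wait waiting think know want need needs "
    "like hope seems appears lying facing kicking swallowing beating done".split()
)
_NOUNS = (
    "baby head brain skull ventricle ventricles cerebellum cavum thalamus "
    "midline falx face profile nose lips lip mouth chin eye eyes orbit orbits "
    "ear neck spine vertebrae back chest thorax heart chamber chambers atrium "
    "aorta valve valves outflow tract lungs lung diaphragm abdomen stomach "
    "bowel kidney kidneys bladder cord insertion vessel vessels artery "
    "arteries vein liver wall genitalia boy girl leg legs knee foot feet toes "
    "arm arms hand hands fingers femur bone bones humerus radius ulna tibia "
    "fibula placenta fluid liquor pocket uterus cervix fundus mum mummy "
    "mother position plane view image picture screen probe transducer gel "
    "machine measurement measurements circumference diameter length size "
    "weight growth centile gestation weeks week days date dates heartbeat "
    "rate beats minute movement movements kick kicks scan section angle "
    "shadow doppler flow colour mode report photo notes appointment midwife "
    "doctor twin twins pregnancy trimester anomaly anatomy structure "
    "structures organ organs marker markers bit moment side end start part "
    "parts area box button couch towel paper gender surprise".split()
)
_OTHER = (
    "i you we it he she they me us your my its his her their of in on at to "
    "from with without over under above below behind between through around "
    "across up down out off now here there just very quite really again so "
    "and or but if then well okay yes no not too also maybe please sorry "
    "almost nearly always sometimes never away along into onto because while "
    "when where what which how today soon once".split()
)

DEFAULT_LEXICON: dict[str, str] = {}
for _words, _tag in (
    (_DETERMINERS, "determiner"),
    (_ADJECTIVES, "adjective"),
    (_VERBS, "verb"),
    (_NOUNS, "noun"),
    (_OTHER, "other"),
):
    for _w in _words:
        if _w in DEFAULT_LEXICON:
            raise RuntimeError(f"duplicate lexicon word {_w!r}")
        DEFAULT_LEXICON[_w] = _tag


@dataclass(frozen=True)
class CorpusStats:
    """Token-level summary of a transcript corpus."""

    pos_fractions: dict[str, float]
    n_unique_words: int
    max_sentence_len: int
    n_tokens: int


def tokenize(sentence: str | Sequence[str]) -> list[str]:
    """Lowercase word tokens with punctuation stripped."""
    if isinstance(sentence, str):
        return _WORD_RE.findall(sentence.lower())
    return [w for raw in sentence for w in _WORD_RE.findall(str(raw).lower())]


def corpus_stats(
    corpus: Iterable[str | Sequence[str]],
    lexicon: Mapping[str, str] | None = None,
) -> CorpusStats:
    """POS fractions, vocabulary size and longest sentence of a corpus.

    ``corpus`` is an iterable of sentences (strings or word lists).  Every
    token must be present in the lexicon; unknown words raise a ``KeyError``
    listing them.
    """
    lexicon = DEFAULT_LEXICON if lexicon is None else lexicon
    counts = {tag: 0 for tag in POS_TAGS}
    vocab: set[str] = set()
    max_len = 0
    n_tokens = 0
    unknown: set[str] = set()
    for sentence in corpus:
        words = tokenize(sentence)
        max_len = max(max_len, len(words))
        for w in words:
            tag = lexicon.get(w)
            if tag is None:
                unknown.add(w)
                continue
            counts[tag] += 1
            vocab.add(w)
            n_tokens += 1
    if unknown:
        raise KeyError(f"words not covered by the lexicon: {sorted(unknown)}")
    if n_tokens == 0:
        raise ValueError("empty corpus")
    return CorpusStats(
        pos_fractions={tag: counts[tag] / n_tokens for tag in POS_TAGS},
        n_unique_words=len(vocab),
        max_sentence_len=max_len,
        n_tokens=n_tokens,
    )


def residual_pos_fraction(fractions_pct: Sequence[float]) -> float:
    """Remainder (percent) after the four tagged POS classes.

    Given the printed adjective/determiner/noun/verb percentages, the
    remainder covers prepositions, pronouns, adverbs and all other parts of
    speech.  Raises if any input is outside [0, 100] or the sum exceeds 100.
    """
    fracs = [float(f) for f in fractions_pct]
    if len(fracs) != 4:
        raise ValueError("expected four percentages (adjective, determiner, noun, verb)")
    for f in fracs:
        if not 0.0 <= f <= 100.0:
            raise ValueError(f"percentage {f} outside [0, 100]")
    total = sum(fracs)
    if total > 100.0 + 1e-9:
        raise ValueError(f"percentages sum to {total} > 100")
    return round(100.0 - total, 6)
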