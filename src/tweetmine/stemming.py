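"""English Snowball (Porter2) stemming.

Implements the English Snowball stemming algorithm ("Porter2"), the standard
suffix-stripping stemmer for English used throughout text-mining pipelines
("resistance" -> "resist", "antibiotics" -> "antibiot").  The implementation
follows the published algorithm definition: prelude (y-marking), regions R1
and R2, steps 0-5 and the exceptional-form tables.

Only lowercase ASCII input is meaningful; tokens are lowercased defensively.
"""

from __future__ import annotations

__all__ = ["stem_word", "stem_tokens"]

_VOWELS = frozenset("aeiouy")
_DOUBLES = ("bb", "dd", "ff", "gg", "mm", "nn", "pp", "rr", "tt")
_LI_ENDINGS = frozenset("cdeghkmnrt")

# Whole-word exceptional forms applied before the main algorithm.
_EXCEPTIONS = {
    "skis": "ski",
    "skies": "sky",
    "dying": "die",
    "lying": "lie",
    "tying": "tie",
    "idly": "idl",
    "gently": "gentl",
    "ugly": "ugli",
    "early": "earli",
    "only": "onli",
    "singly": "singl",
    "sky": "sky",
    "news": "news",
    "howe": "howe",
    "atlas": "atlas",
    "cosmos": "cosmos",
    "bias": "bias",
    "andes": "andes",
}

# Invariant forms checked immediately after step 1a.
_EXCEPTIONS_POST_1A = frozenset(
    {"inning", "outing", "canning", "herring", "earring", "proceed", "exceed", "succeed"}
)

# Words with these prefixes take R1 immediately after the prefix.
_R1_PREFIXES = ("gener", "commun", "arsen")


def _mark_vowel_ys(word: str) -> str:
    # y at the start or after a vowel acts as a consonant; mark it Y.
    chars = list(word)
    for i, c in enumerate(chars):
        if c == "y" and (i == 0 or chars[i - 1] in "aeiouy"):
            chars[i] = "Y"
    return "".join(chars)


def _region_after_vc(word: str, start: int) -> int:
    """Index just past the first non-vowel that follows a vowel, at/after start."""
    i = start
    n = len(word)
    while i < n and word[i] not in "aeiouy":
        i += 1
    while i < n and word[i] in "aeiouy":
        i += 1
    return min(i + 1, n)


def _compute_regions(word: str) -> tuple[int, int]:
    r1 = None
    for pref in _R1_PREFIXES:
        if word.startswith(pref):
            r1 = len(pref)
            break
    if r1 is None:
        r1 = _region_after_vc(word, 0)
    r2 = _region_after_vc(word, r1)
    return r1, r2


def _ends_short_syllable(word: str) -> bool:
    n = len(word)
    if n == 2:
        return word[0] in "aeiouy" and word[1] not in "aeiouy"
    if n >= 3:
        a, b, c = word[-3], word[-2], word[-1]
        return (
            b in "aeiouy"
            and a not in "aeiouy"
            and c not in "aeiouy"
            and c not in "wxY"
        )
    return False


def _contains_vowel(segment: str) -> bool:
    return any(c in "aeiouy" for c in segment)


def stem_word(token: str) -> str:
    """Return the Porter2 stem of a single lowercase token.

    Non-alphabetic tokens (numbers, mixed strings) pass through unchanged
    apart from lowercasing.
    """
    word = token.lower()
    if len(word) <= 2:
        return word
    if word in _EXCEPTIONS:
        return _EXCEPTIONS[word]
    if not word.isalpha():
        return word

    if word.startswith("'"):
        word = word[1:]
    word = _mark_vowel_ys(word)
    r1, r2 = _compute_regions(word)

    # Step 0: apostrophe suffixes.
    for suf in ("'s'", "'s", "'"):
        if word.endswith(suf):
            word = word[: -len(suf)]
            break

    # Step 1a.
    if word.endswith("sses"):
        word = word[:-2]
    elif word.endswith(("ied", "ies")):
        word = word[:-3] + ("i" if len(word) > 4 else "ie")
    elif word.endswith(("us", "ss")):
        pass
    elif word.endswith("s"):
        if _contains_vowel(word[:-2]):
            word = word[:-1]

    if word in _EXCEPTIONS_POST_1A:
        return word.replace("Y", "y")

    # Step 1b.
    step1b_delete = False
    if word.endswith(("eedly", "eed")):
        suf = "eedly" if word.endswith("eedly") else "eed"
        if len(word) - len(suf) >= r1:
            word = word[: -len(suf)] + "ee"
    else:
        for suf in ("ingly", "edly", "ing", "ed"):
            if word.endswith(suf):
                stem = word[: -len(suf)]
                if _contains_vowel(stem):
                    word = stem
                    step1b_delete = True
                break
    if step1b_delete:
        if word.endswith(("at", "bl", "iz")):
            word += "e"
        elif word.endswith(_DOUBLES):
            word = word[:-1]
        elif _ends_short_syllable(word) and r1 >= len(word):
            word += "e"

    # Step 1c: final y/Y -> i after a consonant that is not word-initial.
    if (
        len(word) > 2
        and word[-1] in "yY"
        and word[-2] not in "aeiouy"
    ):
        word = word[:-1] + "i"

    # Step 2 (longest suffix, applied when the suffix lies in R1).
    step2 = (
        ("ization", "ize"),
        ("ational", "ate"),
        ("fulness", "ful"),
        ("ousness", "ous"),
        ("iveness", "ive"),
        ("tional", "tion"),
        ("biliti", "ble"),
        ("lessli", "less"),
        ("entli", "ent"),
        ("ation", "ate"),
        ("alism", "al"),
        ("aliti", "al"),
        ("ousli", "ous"),
        ("iviti", "ive"),
        ("fulli", "ful"),
        ("enci", "ence"),
        ("anci", "ance"),
        ("abli", "able"),
        ("izer", "ize"),
        ("ator", "ate"),
        ("alli", "al"),
        ("bli", "ble"),
    )
    for suf, rep in step2:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                word = word[: -len(suf)] + rep
            break
    else:
        if word.endswith("ogi"):
            if len(word) - 3 >= r1 and len(word) >= 4 and word[-4] == "l":
                word = word[:-1]
        elif word.endswith("li"):
            if len(word) - 2 >= r1 and len(word) >= 3 and word[-3] in _LI_ENDINGS:
                word = word[:-2]

    # Step 3 (suffix in R1; "ative" additionally requires R2).
    step3 = (
        ("ational", "ate"),
        ("tional", "tion"),
        ("alize", "al"),
        ("icate", "ic"),
        ("iciti", "ic"),
        ("ical", "ic"),
        ("ness", ""),
        ("ful", ""),
    )
    matched3 = False
    for suf, rep in step3:
        if word.endswith(suf):
            if len(word) - len(suf) >= r1:
                word = word[: -len(suf)] + rep
            matched3 = True
            break
    if not matched3 and word.endswith("ative"):
        if len(word) - 5 >= r2:
            word = word[:-5]

    # Step 4 (suffix in R2).
    step4 = (
        "ement",
        "ance",
        "ence",
        "able",
        "ible",
        "ment",
        "ant",
        "ent",
        "ism",
        "ate",
        "iti",
        "ous",
        "ive",
        "ize",
        "ion",
        "al",
        "er",
        "ic",
    )
    for suf in step4:
        if word.endswith(suf):
            if len(word) - len(suf) >= r2:
                if suf == "ion":
                    if len(word) >= 4 and word[-4] in "st":
                        word = word[:-3]
                else:
                    word = word[: -len(suf)]
            break

    # Step 5.
    if word.endswith("e"):
        if len(word) - 1 >= r2 or (
            len(word) - 1 >= r1 and not _ends_short_syllable(word[:-1])
        ):
            word = word[:-1]
    elif word.endswith("l"):
        if len(word) - 1 >= r2 and len(word) >= 2 and word[-2] == "l":
            word = word[:-1]

    return word.replace("Y", "y")


def stem_tokens(tokens: list[str]) -> list[str]:
    """Stem each token in a list (element-wise :func:`stem_word`)."""
    return [stem_word(t) for t in tokens]
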