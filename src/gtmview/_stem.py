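"""A compact implementation of the Porter suffix-stripping stemmer.

Standard English suffix stemming ("running", "runs" -> "run") used by the
text preprocessing pipeline.  Follows the original 1980 algorithm: measure-
conditioned suffix rules applied in five steps.
"""

from __future__ import annotations

__all__ = ["porter_stem"]

_VOWELS = set("aeiou")


def _is_cons(word: str, i: int) -> bool:
    c = word[i]
    if c in _VOWELS:
        return False
    if c == "y":
        return i == 0 or not _is_cons(word, i - 1)
    return True


def _measure(stem: str) -> int:
    """Number of VC sequences in the stem."""
    m = 0
    prev_vowel = False
    for i in range(len(stem)):
        cons = _is_cons(stem, i)
        if cons and prev_vowel:
            m += 1
        prev_vowel = not cons
    return m


def _has_vowel(stem: str) -> bool:
    return any(not _is_cons(stem, i) for i in range(len(stem)))


def _ends_double_cons(word: str) -> bool:
    return (len(word) >= 2 and word[-1] == word[-2]
            and _is_cons(word, len(word) - 1))


def _ends_cvc(word: str) -> bool:
    if len(word) < 3:
        return False
    i = len(word) - 1
    if not (_is_cons(word, i) and not _is_cons(word, i - 1)
            and _is_cons(word, i - 2)):
        return False
    return word[i] not in "wxy"


def porter_stem(word: str) -> str:
    w = word.lower()
    if len(w) <= 2:
        return w

    # step 1a
    if w.endswith("sses"):
        w = w[:-2]
    elif w.endswith("ies"):
        w = w[:-2]
    elif w.endswith("ss"):
        pass
    elif w.endswith("s"):
        w = w[:-1]

    # step 1b
    if w.endswith("eed"):
        if _measure(w[:-3]) > 0:
            w = w[:-1]
    else:
        flag = False
        if w.endswith("ed") and _has_vowel(w[:-2]):
            w = w[:-2]
            flag = True
        elif w.endswith("ing") and _has_vowel(w[:-3]):
            w = w[:-3]
            flag = True
        if flag:
            if w.endswith(("at", "bl", "iz")):
                w += "e"
            elif _ends_double_cons(w) and not w.endswith(("l", "s", "z")):
                w = w[:-1]
            elif _measure(w) == 1 and _ends_cvc(w):
                w += "e"

    # step 1c
    if w.endswith("y") and _has_vowel(w[:-1]):
        w = w[:-1] + "i"

    # step 2
    for suf, repl in (("ational", "ate"), ("tional", "tion"), ("enci", "ence"),
                      ("anci", "ance"), ("izer", "ize"), ("abli", "able"),
                      ("alli", "al"), ("entli", "ent"), ("eli", "e"),
                      ("ousli", "ous"), ("ization", "ize"), ("ation", "ate"),
                      ("ator", "ate"), ("alism", "al"), ("iveness", "ive"),
                      ("fulness", "ful"), ("ousness", "ous"), ("aliti", "al"),
                      ("iviti", "ive"), ("biliti", "ble")):
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # step 3
    for suf, repl in (("icate", "ic"), ("ative", ""), ("alize", "al"),
                      ("iciti", "ic"), ("ical", "ic"), ("ful", ""),
                      ("ness", "")):
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if _measure(stem) > 0:
                w = stem + repl
            break

    # step 4
    for suf in ("al", "ance", "ence", "er", "ic", "able", "ible", "ant",
                "ement", "ment", "ent", "ion", "ou", "ism", "ate", "iti",
                "ous", "ive", "ize"):
        if w.endswith(suf):
            stem = w[: -len(suf)]
            if _measure(stem) > 1:
                if suf == "ion" and not stem.endswith(("s", "t")):
                    break
                w = stem
            break

    # step 5a
    if w.endswith("e"):
        stem = w[:-1]
        m = _measure(stem)
        if m > 1 or (m == 1 and not _ends_cvc(stem)):
            w = stem

    # step 5b
    if _measure(w) > 1 and _ends_double_cons(w) and w.endswith("l"):
        w = w[:-1]

    return w
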