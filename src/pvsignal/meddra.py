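"""PT -> SOC term mapping (a two-level stand-in for the MedDRA hierarchy).

Real MedDRA is licensed, so the package accepts any user-supplied two-column
table mapping each Preferred Term (PT) to exactly one System Organ Class
(SOC).  Matching is case-insensitive after whitespace normalization, since
FAERS PT strings vary in casing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import pandas as pd

UNMAPPED = "UNMAPPED"


def _norm(term: str) -> str:
    return " ".join(str(term).split()).lower()


class DictionaryError(ValueError):
    pass


@dataclass
class TermDictionary:
    pt_to_soc: dict[str, str]
    version: str = ""
    #: PTs looked up but absent from the dictionary, tallied across rollups.
    unmapped_seen: set[str] = field(default_factory=set)

    @property
    def socs(self) -> set[str]:
        return set(self.pt_to_soc.values())

    def soc_of(self, pt: str) -> str:
        soc = self.pt_to_soc.get(_norm(pt))
        if soc is None:
            self.unmapped_seen.add(pt)
            return UNMAPPED
        return soc


def build_dictionary(pairs: Iterable[tuple[str, str]], version: str = "") -> TermDictionary:
    mapping: dict[str, str] = {}
    for pt, soc in pairs:
        key = _norm(pt)
        soc = str(soc).strip()
        if key in mapping and mapping[key] != soc:
            raise DictionaryError(
                f"PT {pt!r} mapped to both {mapping[key]!r} and {soc!r}"
            )
        mapping[key] = soc
    if not mapping:
        raise DictionaryError("empty term dictionary")
    return TermDictionary(mapping, version)


def load_dictionary(path: str | Path, version: str = "") -> TermDictionary:
    """Load a PT->SOC table from a TSV/CSV with columns ``pt`` and ``soc``
    (an optional third ``hlt`` column is ignored).  Duplicate PT rows must
    agree on the SOC; a conflict is a hard error."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    if not {"pt", "soc"} <= set(df.columns):
        raise DictionaryError(f"{path}: expected columns 'pt' and 'soc'")
    return build_dictionary(zip(df["pt"], df["soc"]), version=version)


def rollup(
    events: Iterable[tuple[str, str]], dictionary: TermDictionary
) -> list[tuple[str, str]]:
    """Map PT-level (caseid, PT) events to SOC-level (caseid, SOC) events.

    Each PT event contributes exactly one SOC event, so total counts are
    conserved; PTs missing from the dictionary land in SOC ``UNMAPPED``.
    """
    return [(caseid, dictionary.soc_of(pt)) for caseid, pt in events]
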