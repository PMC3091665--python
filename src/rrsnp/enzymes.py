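"""Restriction enzyme definitions for reduced-representation library design.

A candidate enzyme is a blunt-cutting 4-base recognition pattern given in
IUPAC nucleotide code, together with the offset of the blunt cut within the
pattern. Only IUPAC-palindromic patterns are accepted: for such sites a
single forward-strand scan finds every cut on either strand, so the loader
rejects non-palindromic patterns outright rather than silently undercounting.

Methylation sensitivity (e.g. GATC cutters that require an adenine-methylated
site in vivo) is deliberately ignored — digestion here is sequence-only.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, List

#: IUPAC code -> set of concrete bases it matches. An 'N' *base* in a target
#: sequence is never matched by any code (including code N), so recognition
#: sites never span undetermined sequence.
IUPAC_CODES: Dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

_COMPLEMENT = {
    "A": "T", "C": "G", "G": "C", "T": "A", "N": "N",
    "R": "Y", "Y": "R", "S": "S", "W": "W", "K": "M", "M": "K",
    "B": "V", "V": "B", "D": "H", "H": "D",
}

_DNA_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of a plain A/C/G/T/N sequence."""
    return seq.translate(_DNA_COMP)[::-1]


def revcomp_iupac(pattern: str) -> str:
    """Reverse complement of an IUPAC pattern, code-wise."""
    return "".join(_COMPLEMENT[c] for c in reversed(pattern))


def is_iupac_palindrome(pattern: str) -> bool:
    """True when the pattern equals its own IUPAC reverse complement.

    Code-wise equality is exact here because every IUPAC code's complement
    is itself a single IUPAC code (the expansion sets map one-to-one).
    """
    return revcomp_iupac(pattern) == pattern


@dataclass(frozen=True)
class EnzymeSpec:
    """A blunt-cutting restriction enzyme.

    cut_offset is the number of bases from the pattern start to the blunt
    cut position (e.g. TG^CA has cut_offset 2).
    """

    name: str
    recognition: str
    cut_offset: int

    def __post_init__(self):
        object.__setattr__(self, "recognition", self.recognition.upper())
        bad = [c for c in self.recognition if c not in IUPAC_CODES]
        if bad:
            raise ValueError(
                f"enzyme {self.name!r}: invalid IUPAC code(s) {''.join(bad)!r} "
                f"in recognition pattern {self.recognition!r}"
            )
        if not self.recognition:
            raise ValueError(f"enzyme {self.name!r}: empty recognition pattern")
        if not 0 <= self.cut_offset <= len(self.recognition):
            raise ValueError(
                f"enzyme {self.name!r}: cut_offset {self.cut_offset} outside "
                f"pattern of length {len(self.recognition)}"
            )
        if not is_iupac_palindrome(self.recognition):
            raise ValueError(
                f"enzyme {self.name!r}: pattern {self.recognition!r} is not "
                "IUPAC-palindromic; single-strand scanning would miscount cuts"
            )


#: The seven commercial blunt-end 4-cutters evaluated for library design.
BUILTIN_ENZYMES: Dict[str, EnzymeSpec] = {
    e.name: e
    for e in [
        EnzymeSpec("AccII", "CGCG", 2),
        EnzymeSpec("HaeIII", "GGCC", 2),
        EnzymeSpec("RsaI", "GTAC", 2),
        EnzymeSpec("DpnI", "GATC", 2),
        EnzymeSpec("AluI", "AGCT", 2),
        EnzymeSpec("CviRI", "TGCA", 2),
        EnzymeSpec("CviJI", "RGCY", 2),
    ]
}


def load_enzyme_table(path: str | Path) -> List[EnzymeSpec]:
    """Load enzyme definitions from a TSV with columns name/recognition/cut_offset.

    Raises ValueError naming the offending row for malformed IUPAC codes,
    bad offsets, non-palindromic patterns or duplicate names.
    """
    path = Path(path)
    specs: List[EnzymeSpec] = []
    seen = set()
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"name", "recognition", "cut_offset"}
        if reader.fieldnames is None or not required.issubset(reader.fieldnames):
            raise ValueError(
                f"{path}: enzyme table must have columns {sorted(required)}, "
                f"got {reader.fieldnames}"
            )
        for lineno, row in enumerate(reader, start=2):
            try:
                spec = EnzymeSpec(
                    name=row["name"].strip(),
                    recognition=row["recognition"].strip(),
                    cut_offset=int(row["cut_offset"]),
                )
            except (ValueError, TypeError) as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
            if spec.name in seen:
                raise ValueError(f"{path}:{lineno}: duplicate enzyme name {spec.name!r}")
            seen.add(spec.name)
            specs.append(spec)
    return specs


def write_enzyme_table(specs, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("name\trecognition\tcut_offset\n")
        for s in specs:
            fh.write(f"{s.name}\t{s.recognition}\t{s.cut_offset}\n")
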