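"""The 57-analyte dried-blood-spot screening panel.

Newborn-screening MSMS kits quantify a fixed panel of low-molecular-weight
compounds in dried blood spots: amino acids, acylcarnitines, nucleosides,
succinylacetone and lysophosphatidylcholines.  Several assay channels cannot
distinguish isobaric species, so a single measured code such as ``"Gln/Lys"``
or ``"C3DC/C4OH"`` denotes a small set of candidate compounds
("identification variants").  Those combined codes are treated as single
measured variables by every statistical stage; the expansion into variants
happens only in pathway over-representation analysis
(:mod:`neodx.ora`).

The default panel hard-codes every analyte with a published identity and
fills the remaining slots with conventional screening-panel codes flagged
``placeholder=True``; a panel read from a file can replace it wholesale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = ["AnalyteDef", "MetabolitePanel", "default_panel", "CLASSES"]

CLASSES = (
    "amino_acid",
    "acylcarnitine",
    "nucleoside",
    "succinylacetone",
    "lysophosphatidylcholine",
)


@dataclass(frozen=True)
class AnalyteDef:
    """One panel channel.

    Parameters
    ----------
    code : str
        Short label as printed on screening reports (e.g. ``"C3DC/C4OH"``).
    cls : str
        Compound class, one of :data:`CLASSES`.
    variants : tuple of str
        Unambiguous compound names the code may denote.  Codes containing
        ``"/"`` are ambiguous and carry one name per candidate species.
    placeholder : bool
        True for slots filling out the panel to its nominal composition
        whose exact identity is not pinned down by the study itself.
    """

    code: str
    cls: str
    variants: tuple[str, ...]
    placeholder: bool = False

    def __post_init__(self) -> None:
        if self.cls not in CLASSES:
            raise ValueError(f"unknown analyte class {self.cls!r}")
        if not self.variants:
            raise ValueError(f"analyte {self.code!r} has no variants")
        if "/" in self.code and len(self.variants) < 2:
            raise ValueError(
                f"ambiguous code {self.code!r} must have >=2 variants"
            )


@dataclass(frozen=True)
class MetabolitePanel:
    """Ordered catalogue of panel analytes with class and variant metadata."""

    analytes: tuple[AnalyteDef, ...]
    _by_code: dict[str, AnalyteDef] = field(
        init=False, repr=False, compare=False, default_factory=dict
    )

    def __post_init__(self) -> None:
        codes = [a.code for a in self.analytes]
        if len(set(codes)) != len(codes):
            dup = sorted({c for c in codes if codes.count(c) > 1})
            raise ValueError(f"duplicate analyte codes: {dup}")
        object.__setattr__(
            self, "_by_code", {a.code: a for a in self.analytes}
        )

    def __len__(self) -> int:
        return len(self.analytes)

    def __iter__(self) -> Iterator[AnalyteDef]:
        return iter(self.analytes)

    def __contains__(self, code: str) -> bool:
        return code in self._by_code

    @property
    def codes(self) -> list[str]:
        return [a.code for a in self.analytes]

    def __getitem__(self, code: str) -> AnalyteDef:
        try:
            return self._by_code[code]
        except KeyError:
            raise KeyError(f"unknown analyte code {code!r}") from None

    def variants(self, code: str) -> set[str]:
        """Set of candidate compound names behind a measured code."""
        return set(self[code].variants)

    def class_counts(self) -> dict[str, int]:
        counts = {c: 0 for c in CLASSES}
        for a in self.analytes:
            counts[a.cls] += 1
        return counts

    def codes_of_class(self, cls: str) -> list[str]:
        return [a.code for a in self.analytes if a.cls == cls]

    def all_variants(self) -> set[str]:
        """Union of compound names over the whole panel (the ORA universe)."""
        out: set[str] = set()
        for a in self.analytes:
            out |= set(a.variants)
        return out

    def subset(self, codes: list[str]) -> "MetabolitePanel":
        """Panel restricted to ``codes``, keeping their given order."""
        return MetabolitePanel(tuple(self[c] for c in codes))


def _aa(code: str, *variants: str, placeholder: bool = False) -> AnalyteDef:
    return AnalyteDef(code, "amino_acid", variants, placeholder)


def _ac(code: str, *variants: str, placeholder: bool = False) -> AnalyteDef:
    return AnalyteDef(code, "acylcarnitine", variants, placeholder)


_DEFAULT_ANALYTES: tuple[AnalyteDef, ...] = (
    # --- amino acids (14) ---
    _aa("Gly", "glycine"),
    _aa("Ala", "alanine"),
    _aa("Val", "valine"),
    _aa("Leu/Ile/Hyp", "leucine", "isoleucine", "hydroxyproline"),
    _aa("Met", "methionine"),
    _aa("Phe", "phenylalanine"),
    _aa("Tyr", "tyrosine"),
    _aa("Orn", "ornithine"),
    _aa("Cit", "citrulline"),
    _aa("Glu", "glutamate"),
    _aa("Gln/Lys", "glutamine", "lysine"),
    _aa("Arg", "arginine"),
    _aa("ASA", "argininosuccinic acid"),
    _aa("Pro", "proline", placeholder=True),
    # --- acylcarnitines (36) ---
    _ac("C0", "free carnitine", placeholder=True),
    _ac("C2", "acetylcarnitine"),
    _ac("C3", "propionylcarnitine"),
    _ac("C3DC/C4OH", "malonylcarnitine", "3-hydroxybutyrylcarnitine"),
    _ac("C4", "butyrylcarnitine"),
    _ac(
        "C4DC/C5OH",
        "methylmalonylcarnitine",
        "3-hydroxyisovalerylcarnitine",
        placeholder=True,
    ),
    _ac("C5", "valerylcarnitine"),
    _ac("C5:1", "tiglylcarnitine"),
    _ac("C5DC/C6OH", "glutarylcarnitine", "3-hydroxyhexanoylcarnitine"),
    _ac("C6", "hexanoylcarnitine"),
    _ac("C6DC", "methylglutarylcarnitine", placeholder=True),
    _ac("C8", "octanoylcarnitine"),
    _ac("C8:1", "2-octenoylcarnitine"),
    _ac("C10", "decanoylcarnitine", placeholder=True),
    _ac("C10:1", "decenoylcarnitine", placeholder=True),
    _ac("C10:2", "decadienoylcarnitine"),
    _ac("C12", "dodecanoylcarnitine", placeholder=True),
    _ac("C12:1", "dodecenoylcarnitine", placeholder=True),
    _ac("C14", "tetradecanoylcarnitine"),
    _ac("C14:1", "tetradecenoylcarnitine"),
    _ac("C14:2", "tetradecadienoylcarnitine"),
    _ac("C14OH", "3-hydroxytetradecanoylcarnitine", placeholder=True),
    _ac("C16", "hexadecanoylcarnitine", placeholder=True),
    _ac("C16:1", "hexadecenoylcarnitine", placeholder=True),
    _ac("C16OH", "3-hydroxyhexadecanoylcarnitine", placeholder=True),
    _ac("C16:1OH", "3-hydroxyhexadecenoylcarnitine", placeholder=True),
    _ac("C18", "octadecanoylcarnitine"),
    _ac("C18:1", "octadecenoylcarnitine", placeholder=True),
    _ac("C18:2", "octadecadienoylcarnitine"),
    _ac("C18OH", "3-hydroxyoctadecanoylcarnitine", placeholder=True),
    _ac("C18:1OH", "3-hydroxyoctadecenoylcarnitine", placeholder=True),
    _ac("C18:2OH", "3-hydroxyoctadecadienoylcarnitine", placeholder=True),
    _ac("C20", "arachidoylcarnitine"),
    _ac("C22", "docosanoylcarnitine", placeholder=True),
    _ac("C24", "lignoceroylcarnitine"),
    _ac("C26", "hexacosanoylcarnitine"),
    # --- nucleosides (2) ---
    AnalyteDef("Ado", "nucleoside", ("adenosine",), placeholder=True),
    AnalyteDef("d-Ado", "nucleoside", ("deoxyadenosine",)),
    # --- succinylacetone (1) ---
    AnalyteDef("SA", "succinylacetone", ("succinylacetone",)),
    # --- lysophosphatidylcholines (4) ---
    AnalyteDef(
        "LPC C20:0",
        "lysophosphatidylcholine",
        ("lysophosphatidylcholine C20:0",),
    ),
    AnalyteDef(
        "LPC C22:0",
        "lysophosphatidylcholine",
        ("lysophosphatidylcholine C22:0",),
    ),
    AnalyteDef(
        "LPC C24:0",
        "lysophosphatidylcholine",
        ("lysophosphatidylcholine C24:0",),
    ),
    AnalyteDef(
        "LPC C26:0",
        "lysophosphatidylcholine",
        ("lysophosphatidylcholine C26:0",),
    ),
)


def default_panel() -> MetabolitePanel:
    """The built-in 57-analyte panel.

    Composition: 14 amino acids, 36 acylcarnitines, 2 nucleosides,
    succinylacetone and 4 lysophosphatidylcholines.  Every analyte with a
    published identity is present under its printed code; the remaining
    slots carry conventional screening codes marked ``placeholder=True``.
    """
    return MetabolitePanel(_DEFAULT_ANALYTES)
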