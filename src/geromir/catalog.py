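"""Literature-curated geromiR catalog with hallmark-of-aging annotations.

geromiRs are miRNAs implicated in the aging process.  The catalog merges
three published review compilations into a single table of harmonized
miRNA names, each annotated with one or more hallmarks of aging and with
the reviews that mention it.  A second, platform-restricted view records
which geromiRs are represented on the microarray and which of those were
called significantly downregulated in the tumor microenvironment.
"""

from __future__ import annotations

import re
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import pandas as pd

__all__ = [
    "Hallmark",
    "HALLMARKS",
    "HALLMARK_NAMES",
    "InvalidMiRNANameError",
    "VocabularyError",
    "GeromiRRecord",
    "GeromiRCatalog",
    "normalize_mirna_name",
    "build_catalog",
    "restrict_to_platform",
    "hallmark_members",
    "load_source_tables",
    "load_platform_table",
    "reference_catalog",
    "platform_catalog",
]


class InvalidMiRNANameError(ValueError):
    """Raised for empty or unrecognizable miRNA tokens."""


class VocabularyError(KeyError):
    """Raised when a hallmark name is outside the controlled vocabulary."""


@dataclass(frozen=True)
class Hallmark:
    """One hallmark-of-aging category.

    ``code`` is a unique internal identifier; ``display_letter`` is the
    single-letter label used in published figure legends.  The printed
    letters collide (uppercase ``S`` is reused for splicing and
    senescence; the lowercase s/h/i family collides with their uppercase
    twins case-insensitively), so the letters are display-only and the
    codes are the keys.
    """

    code: str
    name: str
    display_letter: str


#: Controlled vocabulary: the 15 hallmark categories of the compilation.
HALLMARKS: tuple[Hallmark, ...] = (
    Hallmark("DDR", "altered DNA damage response", "D"),
    Hallmark("TEL", "loss of telomeres", "T"),
    Hallmark("MET", "DNA methylation", "M"),
    Hallmark("HIS", "histone modifications", "H"),
    Hallmark("SPL", "regulation of splicing", "S"),
    Hallmark("PRO", "changes to protein homeostasis", "P"),
    Hallmark("NUT", "altered nutrient sensing", "N"),
    Hallmark("MIT", "mitochondrial dysfunction", "m"),
    Hallmark("SEN", "cellular senescence", "S"),
    Hallmark("SCE", "stem cell exhaustion", "E"),
    Hallmark("INF", "inflammaging", "I"),
    Hallmark("SIR", "epigenetic alterations (Sirtuins)", "s"),
    Hallmark("SCH", "stem cell homeostasis", "h"),
    Hallmark("IGF", "insulin/IGF1", "i"),
    Hallmark("ICC", "altered intercellular communication", "C"),
)

HALLMARK_NAMES: tuple[str, ...] = tuple(h.name for h in HALLMARKS)
_BY_NAME: dict[str, Hallmark] = {h.name.lower(): h for h in HALLMARKS}
_BY_CODE: dict[str, Hallmark] = {h.code: h for h in HALLMARKS}


def get_hallmark(key: str | Hallmark) -> Hallmark:
    """Resolve a hallmark by code, name (case-insensitive) or identity."""
    if isinstance(key, Hallmark):
        return key
    if key in _BY_CODE:
        return _BY_CODE[key]
    try:
        return _BY_NAME[key.strip().lower()]
    except (KeyError, AttributeError):
        raise VocabularyError(f"unknown hallmark: {key!r}") from None


_MARKUP = " \t\r\n*_'\"`,;:()[]"
_NAME_RE = re.compile(
    r"^(?:(?P<species>[A-Za-z]{3,4})-)?(?P<stem>miR|let|lin)-?(?P<rest>\S+)$",
    re.IGNORECASE,
)
_STEM_CASE = {"mir": "miR", "let": "let", "lin": "lin"}


def normalize_mirna_name(raw: str) -> str:
    """Harmonize a free-text miRNA token to catalog spelling.

    Strips surrounding whitespace/markup and any species prefix
    (``hsa-``, ``mmu-``, ...), unifies the stem capitalization to
    ``miR-``/``let-``/``lin-`` and preserves the numeric/letter/arm
    suffix verbatim.  Idempotent.
    """
    if not isinstance(raw, str):
        raise InvalidMiRNANameError(f"not a string: {raw!r}")
    token = raw.strip(_MARKUP)
    if not token:
        raise InvalidMiRNANameError(f"empty or all-markup token: {raw!r}")
    m = _NAME_RE.match(token)
    if m is None:
        raise InvalidMiRNANameError(f"unrecognized miRNA token: {raw!r}")
    stem = _STEM_CASE[m.group("stem").lower()]
    return f"{stem}-{m.group('rest')}"


@dataclass(frozen=True)
class GeromiRRecord:
    """One harmonized geromiR with its annotations and provenance."""

    canonical_name: str
    hallmarks: frozenset[str]          # hallmark codes
    sources: frozenset[str]
    on_platform: bool = False
    downregulated_flag: bool = False

    def __post_init__(self) -> None:
        if not self.hallmarks:
            raise ValueError(f"{self.canonical_name}: empty hallmark set")
        if not self.sources:
            raise ValueError(f"{self.canonical_name}: empty source set")
        unknown = set(self.hallmarks) - set(_BY_CODE)
        if unknown:
            raise VocabularyError(f"unknown hallmark codes: {sorted(unknown)}")
        if self.downregulated_flag and not self.on_platform:
            raise ValueError(
                f"{self.canonical_name}: downregulated_flag requires on_platform"
            )

    def hallmark_names(self) -> frozenset[str]:
        return frozenset(_BY_CODE[c].name for c in self.hallmarks)


class GeromiRCatalog:
    """Collection of :class:`GeromiRRecord` keyed by canonical name."""

    def __init__(self, records: Iterable[GeromiRRecord] = ()) -> None:
        self._records: dict[str, GeromiRRecord] = {}
        for rec in records:
            if rec.canonical_name in self._records:
                raise ValueError(f"duplicate canonical name: {rec.canonical_name}")
            self._records[rec.canonical_name] = rec

    def __len__(self) -> int:
        return len(self._records)

    def __contains__(self, name: str) -> bool:
        return name in self._records

    def __getitem__(self, name: str) -> GeromiRRecord:
        return self._records[name]

    def __iter__(self):
        return iter(self._records.values())

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GeromiRCatalog):
            return NotImplemented
        return self._records == other._records

    @property
    def names(self) -> frozenset[str]:
        return frozenset(self._records)

    @property
    def on_platform_names(self) -> frozenset[str]:
        return frozenset(n for n, r in self._records.items() if r.on_platform)

    @property
    def downregulated_names(self) -> frozenset[str]:
        return frozenset(
            n for n, r in self._records.items() if r.downregulated_flag
        )

    def with_flags(
        self,
        on_platform: Iterable[str] | None = None,
        downregulated: Iterable[str] | None = None,
    ) -> "GeromiRCatalog":
        """Return a copy with platform/downregulation flags set by name."""
        plat = set(on_platform) if on_platform is not None else None
        down = set(downregulated) if downregulated is not None else set()
        out = []
        for rec in self:
            is_plat = rec.on_platform if plat is None else rec.canonical_name in plat
            is_down = rec.canonical_name in down
            out.append(
                GeromiRRecord(
                    rec.canonical_name, rec.hallmarks, rec.sources,
                    on_platform=is_plat or is_down,
                    downregulated_flag=is_down,
                )
            )
        return GeromiRCatalog(out)

    # -- serialization: one row per (miRNA, hallmark, source) triple -------
    def to_frame(self) -> pd.DataFrame:
        rows = []
        for rec in sorted(self, key=lambda r: r.canonical_name):
            for code in sorted(rec.hallmarks):
                for src in sorted(rec.sources):
                    rows.append(
                        (rec.canonical_name, _BY_CODE[code].name, src,
                         int(rec.on_platform), int(rec.downregulated_flag))
                    )
        return pd.DataFrame(
            rows,
            columns=["canonical_name", "hallmark", "source",
                     "on_platform", "downregulated_flag"],
        )

    def write_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GeromiRCatalog":
        df = pd.read_csv(path, sep="\t", dtype=str)
        required = {"canonical_name", "hallmark", "source",
                    "on_platform", "downregulated_flag"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"catalog file missing columns: {sorted(missing)}")
        records = []
        for name, grp in df.groupby("canonical_name", sort=True):
            records.append(
                GeromiRRecord(
                    canonical_name=str(name),
                    hallmarks=frozenset(
                        get_hallmark(h).code for h in grp["hallmark"]
                    ),
                    sources=frozenset(grp["source"]),
                    on_platform=bool(grp["on_platform"].astype(int).any()),
                    downregulated_flag=bool(
                        grp["downregulated_flag"].astype(int).any()
                    ),
                )
            )
        return cls(records)


def build_catalog(
    source_tables: Mapping[str, Mapping[str, Sequence[str]]],
) -> GeromiRCatalog:
    """Merge per-source hallmark tables into one harmonized catalog.

    ``source_tables`` maps source identifier -> {hallmark name -> raw
    miRNA tokens}.  Names are normalized then deduplicated; hallmark and
    source sets are unions over all occurrences.  Distinct printed
    tokens remain distinct miRNAs (``miR-34`` is not ``miR-34a``).
    """
    hallmarks: dict[str, set[str]] = {}
    sources: dict[str, set[str]] = {}
    for source, table in source_tables.items():
        for hallmark, tokens in table.items():
            code = get_hallmark(hallmark).code
            for tok in tokens:
                name = normalize_mirna_name(tok)
                hallmarks.setdefault(name, set()).add(code)
                sources.setdefault(name, set()).add(source)
    return GeromiRCatalog(
        GeromiRRecord(name, frozenset(hallmarks[name]), frozenset(sources[name]))
        for name in hallmarks
    )


def restrict_to_platform(
    catalog: GeromiRCatalog, platform_mirnas: Iterable[str]
) -> GeromiRCatalog:
    """Keep exactly the records whose name is on the platform.

    Platform identifiers must already be normalized.  Survivors get
    ``on_platform=True``; an empty intersection is a valid empty catalog.
    """
    platform = set(platform_mirnas)
    return GeromiRCatalog(
        GeromiRRecord(
            rec.canonical_name, rec.hallmarks, rec.sources,
            on_platform=True, downregulated_flag=rec.downregulated_flag,
        )
        for rec in catalog
        if rec.canonical_name in platform
    )


def hallmark_members(
    catalog: GeromiRCatalog, hallmark: str | Hallmark
) -> frozenset[str]:
    """Canonical names annotated with the given hallmark."""
    code = get_hallmark(hallmark).code
    return frozenset(
        rec.canonical_name for rec in catalog if code in rec.hallmarks
    )


# -- packaged compilation fixtures -----------------------------------------

def _data_path(name: str) -> Path:
    return Path(str(resources.files("geromir.data").joinpath(name)))


def load_source_tables() -> dict[str, dict[str, list[str]]]:
    """Per-source hallmark tables transcribed from the three reviews."""
    df = pd.read_csv(_data_path("geromir_sources.tsv"), sep="\t", dtype=str)
    out: dict[str, dict[str, list[str]]] = {}
    for (source, hallmark), grp in df.groupby(["source", "hallmark"], sort=False):
        out.setdefault(str(source), {})[str(hallmark)] = list(grp["mirna"])
    return out


def load_platform_table() -> pd.DataFrame:
    """Platform-represented geromiRs with their downregulation flags.

    One row per (hallmark, miRNA); ``downregulated`` is 1 for the
    geromiRs called significantly down in the tumor microenvironment.
    """
    df = pd.read_csv(_data_path("platform_geromirs.tsv"), sep="\t", dtype=str)
    df["mirna"] = df["mirna"].map(normalize_mirna_name)
    df["downregulated"] = df["downregulated"].astype(int)
    return df


def reference_catalog() -> GeromiRCatalog:
    """The full 115-geromiR compilation with platform/downregulation flags."""
    cat = build_catalog(load_source_tables())
    plat = load_platform_table()
    return cat.with_flags(
        on_platform=set(plat["mirna"]),
        downregulated=set(plat.loc[plat["downregulated"] == 1, "mirna"]),
    )


def platform_catalog() -> GeromiRCatalog:
    """The 75 platform-represented geromiRs, annotated per the platform table.

    Hallmark assignments follow the platform-restricted compilation
    (which reshuffles a few annotations relative to the full table);
    source provenance is inherited from the full catalog.
    """
    full = build_catalog(load_source_tables())
    plat = load_platform_table()
    records = []
    for mirna, grp in plat.groupby("mirna", sort=True):
        name = str(mirna)
        records.append(
            GeromiRRecord(
                canonical_name=name,
                hallmarks=frozenset(get_hallmark(h).code for h in grp["hallmark"]),
                sources=full[name].sources if name in full else frozenset({"platform"}),
                on_platform=True,
                downregulated_flag=bool(grp["downregulated"].any()),
            )
        )
    return GeromiRCatalog(records)
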