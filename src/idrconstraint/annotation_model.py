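"""Domain types, table IO, and the disordered/non-annotated residue partition.

Coordinates are 1-based and inclusive on every public interface, following
the UniProt/DisProt convention. A protein residue is "disordered" (DR) iff it
is covered by at least one experimentally annotated disordered region (IDR);
every other residue of a studied protein is "non-annotated" (NR). No attempt
is made to predict order/disorder for NR residues.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable, Sequence

import numpy as np
import pandas as pd

#: The 25 UniProt sequence-feature classes analysed throughout the package,
#: in canonical order. All feature vectors and enrichment scans use this order.
FEATURE_CLASSES: tuple[str, ...] = (
    "active site",
    "metal binding site",
    "binding site",
    "site",
    "DNA binding region",
    "nucleotide phosphate binding region",
    "zinc finger",
    "Ca binding region",
    "region of interest",
    "repeat",
    "coiled coil",
    "motif",
    "domain",
    "topological domain",
    "transmembrane",
    "intramembrane",
    "peptide",
    "propeptide",
    "transit peptide",
    "signal peptide",
    "modified residue",
    "lipidation",
    "glycosylation",
    "disulfide bond",
    "cross-link",
)

#: Protein-changing variant types plus the silent class.
VARIANT_TYPES: tuple[str, ...] = (
    "missense",
    "synonymous",
    "nonsense",
    "frameshift",
    "inframe",
)
#: The four types for which pathogenic/population burden is compared.
PROTEIN_CHANGING_TYPES: tuple[str, ...] = (
    "missense",
    "nonsense",
    "frameshift",
    "inframe",
)

VARIANT_SOURCES = ("population", "pathogenic_db")
SIGNIFICANCE_LEVELS = ("pathogenic", "benign", "vus", "none")

#: Disorder-ontology category axes carried by a region.
CATEGORY_AXES = ("function", "partner", "transition", "state")

#: UniProt GFF column-3 "type" tokens mapped onto the canonical 25 classes.
GFF_TYPE_ALIASES: dict[str, str] = {
    "active site": "active site",
    "metal binding": "metal binding site",
    "metal ion-binding site": "metal binding site",
    "binding site": "binding site",
    "site": "site",
    "dna binding": "DNA binding region",
    "dna-binding region": "DNA binding region",
    "nucleotide binding": "nucleotide phosphate binding region",
    "nucleotide phosphate-binding region": "nucleotide phosphate binding region",
    "zinc finger": "zinc finger",
    "zinc finger region": "zinc finger",
    "calcium binding": "Ca binding region",
    "calcium-binding region": "Ca binding region",
    "region": "region of interest",
    "region of interest": "region of interest",
    "repeat": "repeat",
    "coiled coil": "coiled coil",
    "coiled-coil region": "coiled coil",
    "motif": "motif",
    "short sequence motif": "motif",
    "domain": "domain",
    "topological domain": "topological domain",
    "transmembrane": "transmembrane",
    "transmembrane region": "transmembrane",
    "intramembrane": "intramembrane",
    "intramembrane region": "intramembrane",
    "peptide": "peptide",
    "propeptide": "propeptide",
    "transit peptide": "transit peptide",
    "signal peptide": "signal peptide",
    "signal": "signal peptide",
    "modified residue": "modified residue",
    "lipidation": "lipidation",
    "lipid moiety-binding region": "lipidation",
    "glycosylation": "glycosylation",
    "glycosylation site": "glycosylation",
    "disulfide bond": "disulfide bond",
    "cross-link": "cross-link",
    "crosslink": "cross-link",
}

_SIGNIFICANCE_ALIASES = {
    "pathogenic": "pathogenic",
    "likely pathogenic": "pathogenic",
    "likely-pathogenic": "pathogenic",
    "likely_pathogenic": "pathogenic",
    "benign": "benign",
    "likely benign": "benign",
    "likely-benign": "benign",
    "likely_benign": "benign",
    "vus": "vus",
    "uncertain significance": "vus",
    "uncertain_significance": "vus",
    "uncertain": "vus",
    "none": "none",
    "": "none",
}


class AnnotationError(ValueError):
    """Malformed record in an annotation table (carries the offending row)."""


@dataclass(frozen=True)
class ProteinRecord:
    accession: str
    gene: str
    length: int

    def __post_init__(self) -> None:
        if self.length < 1:
            raise AnnotationError(
                f"protein {self.accession!r}: length must be >= 1, got {self.length}"
            )


@dataclass(frozen=True)
class DisorderRegion:
    """One annotated IDR, optionally labelled with disorder-ontology categories."""

    region_id: str
    accession: str
    start: int
    end: int
    gene: str = ""
    function_category: str = ""
    partner_category: str = ""
    transition_category: str = ""
    state_category: str = ""

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"region {self.region_id!r}: invalid coordinates "
                f"start={self.start}, end={self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    def category(self, axis: str) -> str:
        if axis not in CATEGORY_AXES:
            raise ValueError(f"unknown category axis {axis!r}")
        return getattr(self, f"{axis}_category")


@dataclass(frozen=True)
class FeatureAnnotation:
    """A UniProt sequence feature; point sites have start == end."""

    accession: str
    feature_class: str
    start: int
    end: int
    description: str = ""

    def __post_init__(self) -> None:
        if self.feature_class not in FEATURE_CLASSES:
            raise AnnotationError(f"unknown feature class {self.feature_class!r}")
        if not (1 <= self.start <= self.end):
            raise AnnotationError(
                f"feature {self.feature_class!r} on {self.accession}: invalid "
                f"coordinates start={self.start}, end={self.end}"
            )


@dataclass(frozen=True)
class VariantRecord:
    """One protein-coordinate variant.

    Indels are anchored at their first affected residue; a variant belongs to
    a region iff that anchor residue lies within the region. Population
    records carry an allele count; clinical-database records carry a
    significance level.
    """

    accession: str
    position: int
    vtype: str
    source: str
    allele_count: int | None = None
    significance: str = "none"
    phenotype: str = ""

    def __post_init__(self) -> None:
        if self.vtype not in VARIANT_TYPES:
            raise AnnotationError(f"unknown variant type {self.vtype!r}")
        if self.source not in VARIANT_SOURCES:
            raise AnnotationError(f"unknown variant source {self.source!r}")
        if self.position < 1:
            raise AnnotationError(f"invalid variant position {self.position}")
        if self.source == "population" and self.allele_count is None:
            raise AnnotationError("population variant without allele_count")
        if self.significance not in SIGNIFICANCE_LEVELS:
            raise AnnotationError(f"unknown significance {self.significance!r}")


@dataclass
class ResiduePartition:
    """Boolean DR mask per protein; True marks a disordered residue."""

    masks: dict[str, np.ndarray] = field(default_factory=dict)

    @property
    def n_DR(self) -> int:
        return int(sum(int(m.sum()) for m in self.masks.values()))

    @property
    def n_NR(self) -> int:
        return int(sum(m.size - int(m.sum()) for m in self.masks.values()))

    @property
    def n_total(self) -> int:
        return int(sum(m.size for m in self.masks.values()))

    def is_disordered(self, accession: str, position: int) -> bool:
        mask = self.masks[accession]
        if not (1 <= position <= mask.size):
            raise AnnotationError(
                f"position {position} outside protein {accession} "
                f"(length {mask.size})"
            )
        return bool(mask[position - 1])


# ---------------------------------------------------------------------------
# Table IO

REGION_COLUMNS = [
    "region_id",
    "accession",
    "gene",
    "start",
    "end",
    "function_category",
    "partner_category",
    "transition_category",
    "state_category",
]
FEATURE_COLUMNS = ["accession", "feature_class", "start", "end", "description"]
VARIANT_COLUMNS = [
    "accession",
    "position",
    "vtype",
    "source",
    "allele_count",
    "significance",
    "phenotype",
]


def _read_tsv(source: str | IO[str], columns: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ("accession", "start", "end") if c in columns and c not in df.columns]
    if missing:
        raise AnnotationError(f"missing required columns: {missing}")
    return df


def read_proteins(source: str | IO[str]) -> list[ProteinRecord]:
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    out = []
    seen: set[str] = set()
    for i, row in enumerate(df.itertuples(index=False), start=2):
        acc = row.accession
        if acc in seen:
            raise AnnotationError(f"row {i}: duplicate accession {acc!r}")
        seen.add(acc)
        out.append(ProteinRecord(acc, getattr(row, "gene", ""), int(row.length)))
    return out


def read_regions(
    source: str | IO[str],
    dialect: str = "tsv",
    proteins: Sequence[ProteinRecord] | None = None,
) -> list[DisorderRegion]:
    """Read a DisProt-style region table (TSV or JSON records).

    Coordinates are validated against protein lengths when ``proteins`` is
    given. Unknown category labels are kept verbatim with a warning; rows
    with malformed coordinates raise :class:`AnnotationError` naming the row.
    """
    if dialect == "tsv":
        df = _read_tsv(source, REGION_COLUMNS)
    elif dialect == "json":
        df = pd.read_json(source, dtype=str).fillna("")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    lengths = {p.accession: p.length for p in proteins} if proteins else None
    out: list[DisorderRegion] = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        try:
            start, end = int(row["start"]), int(row["end"])
        except (KeyError, ValueError) as exc:
            raise AnnotationError(f"row {i}: malformed coordinates: {exc}") from None
        try:
            region = DisorderRegion(
                region_id=str(row.get("region_id") or f"{row['accession']}:{start}-{end}"),
                accession=str(row["accession"]),
                gene=str(row.get("gene", "")),
                start=start,
                end=end,
                function_category=str(row.get("function_category", "")),
                partner_category=str(row.get("partner_category", "")),
                transition_category=str(row.get("transition_category", "")),
                state_category=str(row.get("state_category", "")),
            )
        except AnnotationError as exc:
            raise AnnotationError(f"row {i}: {exc}") from None
        if lengths is not None:
            if region.accession not in lengths:
                raise AnnotationError(
                    f"row {i}: region {region.region_id!r} references unknown "
                    f"protein {region.accession!r}"
                )
            if region.end > lengths[region.accession]:
                raise AnnotationError(
                    f"row {i}: region {region.region_id!r} extends past protein "
                    f"end ({region.end} > {lengths[region.accession]})"
                )
        out.append(region)
    return out


def write_regions(regions: Iterable[DisorderRegion], target: str | IO[str]) -> None:
    df = pd.DataFrame(
        [
            {
                "region_id": r.region_id,
                "accession": r.accession,
                "gene": r.gene,
                "start": r.start,
                "end": r.end,
                "function_category": r.function_category,
                "partner_category": r.partner_category,
                "transition_category": r.transition_category,
                "state_category": r.state_category,
            }
            for r in regions
        ],
        columns=REGION_COLUMNS,
    )
    df.to_csv(target, sep="\t", index=False)


def read_features(
    source: str | IO[str],
    dialect: str = "tsv",
    proteins: Sequence[ProteinRecord] | None = None,
) -> tuple[list[FeatureAnnotation], int]:
    """Read a feature table; returns (features, n_dropped).

    ``tsv`` expects canonical class names; ``uniprot_gff`` maps GFF column 3
    through :data:`GFF_TYPE_ALIASES`. Classes outside the 25 studied ones are
    dropped and counted. Point features are normalised to start == end by
    construction (start == end rows).
    """
    if dialect == "tsv":
        df = _read_tsv(source, FEATURE_COLUMNS)
        rows = [
            (str(r["accession"]), str(r["feature_class"]), r["start"], r["end"],
             str(r.get("description", "")))
            for r in df.to_dict("records")
        ]
    elif dialect == "uniprot_gff":
        if isinstance(source, str):
            with open(source) as fh:
                text = fh.read()
        else:
            text = source.read()
        rows = []
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise AnnotationError(f"malformed GFF line: {line!r}")
            rows.append((parts[0], parts[2], parts[3], parts[4], ""))
    else:
        raise ValueError(f"unknown dialect {dialect!r}")

    lengths = {p.accession: p.length for p in proteins} if proteins else None
    out: list[FeatureAnnotation] = []
    dropped = 0
    for i, (acc, klass, start, end, desc) in enumerate(rows, start=2):
        if dialect == "uniprot_gff":
            mapped = GFF_TYPE_ALIASES.get(klass.strip().lower())
        else:
            mapped = klass if klass in FEATURE_CLASSES else None
        if mapped is None:
            dropped += 1
            continue
        try:
            s, e = int(start), int(end)
        except ValueError as exc:
            raise AnnotationError(f"row {i}: malformed coordinates: {exc}") from None
        feat = FeatureAnnotation(acc, mapped, s, e, desc)
        if lengths is not None and acc in lengths and e > lengths[acc]:
            raise AnnotationError(
                f"row {i}: feature {mapped!r} extends past protein end of {acc}"
            )
        out.append(feat)
    if dropped:
        warnings.warn(f"dropped {dropped} feature rows outside the 25 studied classes")
    return out, dropped


def write_features(features: Iterable[FeatureAnnotation], target: str | IO[str],
                   dialect: str = "tsv") -> None:
    if dialect == "tsv":
        df = pd.DataFrame(
            [
                {
                    "accession": f.accession,
                    "feature_class": f.feature_class,
                    "start": f.start,
                    "end": f.end,
                    "description": f.description,
                }
                for f in features
            ],
            columns=FEATURE_COLUMNS,
        )
        df.to_csv(target, sep="\t", index=False)
    elif dialect == "uniprot_gff":
        lines = [
            "\t".join([f.accession, "UniProtKB", f.feature_class, str(f.start),
                       str(f.end), ".", ".", ".", f"Note={f.description}"])
            for f in features
        ]
        text = "##gff-version 3\n" + "\n".join(lines) + "\n"
        if isinstance(target, str):
            with open(target, "w") as fh:
                fh.write(text)
        else:
            target.write(text)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def read_variants(source: str | IO[str]) -> list[VariantRecord]:
    """Read a protein-coordinate variant table.

    "likely pathogenic"/"likely benign"/"uncertain significance" labels are
    folded into pathogenic/benign/vus; rows with an unknown variant type are
    rejected with their row number.
    """
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    out: list[VariantRecord] = []
    for i, row in enumerate(df.to_dict("records"), start=2):
        vtype = str(row["vtype"]).strip().lower()
        if vtype not in VARIANT_TYPES:
            raise AnnotationError(f"row {i}: unknown variant type {row['vtype']!r}")
        sig_raw = str(row.get("significance", "")).strip().lower()
        if sig_raw not in _SIGNIFICANCE_ALIASES:
            raise AnnotationError(f"row {i}: unknown significance {sig_raw!r}")
        ac_raw = str(row.get("allele_count", "")).strip()
        out.append(
            VariantRecord(
                accession=str(row["accession"]),
                position=int(row["position"]),
                vtype=vtype,
                source=str(row["source"]).strip(),
                allele_count=int(ac_raw) if ac_raw else None,
                significance=_SIGNIFICANCE_ALIASES[sig_raw],
                phenotype=str(row.get("phenotype", "")),
            )
        )
    return out


def write_variants(variants: Iterable[VariantRecord], target: str | IO[str]) -> None:
    df = pd.DataFrame(
        [
            {
                "accession": v.accession,
                "position": v.position,
                "vtype": v.vtype,
                "source": v.source,
                "allele_count": "" if v.allele_count is None else v.allele_count,
                "significance": v.significance,
                "phenotype": v.phenotype,
            }
            for v in variants
        ],
        columns=VARIANT_COLUMNS,
    )
    df.to_csv(target, sep="\t", index=False)


def write_proteins(proteins: Iterable[ProteinRecord], target: str | IO[str]) -> None:
    df = pd.DataFrame(
        [{"accession": p.accession, "gene": p.gene, "length": p.length} for p in proteins],
        columns=["accession", "gene", "length"],
    )
    df.to_csv(target, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Residue partition


def build_partition(
    proteins: Sequence[ProteinRecord], regions: Sequence[DisorderRegion]
) -> ResiduePartition:
    """Union of region intervals per protein.

    Every region must reference a supplied protein and lie within its bounds;
    proteins without any region contribute all-NR residues. Duplicated or
    overlapping regions are harmless (set union).
    """
    masks = {p.accession: np.zeros(p.length, dtype=bool) for p in proteins}
    for region in regions:
        if region.accession not in masks:
            raise AnnotationError(
                f"region {region.region_id!r}: no protein record for "
                f"{region.accession!r}"
            )
        mask = masks[region.accession]
        if region.end > mask.size:
            raise AnnotationError(
                f"region {region.region_id!r} extends past protein end "
                f"({region.end} > {mask.size})"
            )
        mask[region.start - 1 : region.end] = True
    return ResiduePartition(masks=masks)


def regions_to_tsv_string(regions: Iterable[DisorderRegion]) -> str:
    buf = io.StringIO()
    write_regions(regions, buf)
    return buf.getvalue()
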