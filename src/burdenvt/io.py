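"""Reading and writing the tabular cohort formats.

The native format is three TSV tables — individuals, variants, genotypes —
either as three files in a directory::

    individuals.tsv   individual_id  status  cohort_label  bmi
    variants.tsv      variant_id  protein_pos  func_class  [notes]
    genotypes.tsv     individual_id  variant_id  allele_count

or as three stanzas in a single ``.tsv`` file, each introduced by a marker
line ``#[individuals]`` / ``#[variants]`` / ``#[genotypes]`` followed by its
header row.  Missing BMI is an empty field.  Parsing is line-oriented so
errors can name the offending line.

A minimal single-gene VCF reader is provided for convenience: it expects
GT-only sample columns and an INFO key ``CSQ=func_class|protein_pos``;
case/control status and cohort labels are not representable in VCF and must
be supplied as an individuals table.
"""

from __future__ import annotations

import csv
import io as _io
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

from .errors import ParseError
from .model import (
    Cohort,
    GenotypeEntry,
    Individual,
    RegionAnnotation,
    VariantRecord,
)

_STANZAS = ("individuals", "variants", "genotypes")
_IND_COLS = ("individual_id", "status", "cohort_label", "bmi")
_VAR_COLS = ("variant_id", "protein_pos", "func_class")
_GT_COLS = ("individual_id", "variant_id", "allele_count")

PathLike = Union[str, Path]


def _parse_rows(name: str, lines: list[tuple[int, str]], required: tuple[str, ...]):
    """Parse one stanza's lines [(lineno, text), ...] into dict rows."""
    if not lines:
        raise ParseError(f"{name} table is empty")
    header_no, header = lines[0]
    cols = header.rstrip("\n").split("\t")
    missing = [c for c in required if c not in cols]
    if missing:
        raise ParseError(
            f"line {header_no}: {name} header missing column(s) {missing}"
        )
    rows = []
    for lineno, text in lines[1:]:
        text = text.rstrip("\n")
        if not text.strip():
            continue
        fields = text.split("\t")
        if len(fields) != len(cols):
            raise ParseError(
                f"line {lineno}: expected {len(cols)} fields in {name} row, "
                f"got {len(fields)}"
            )
        rows.append((lineno, dict(zip(cols, fields))))
    return rows


def _build_cohort(ind_rows, var_rows, gt_rows) -> Cohort:
    individuals = []
    for lineno, row in ind_rows:
        try:
            bmi_field = row.get("bmi", "")
            individuals.append(
                Individual(
                    individual_id=row["individual_id"],
                    status=row["status"],
                    cohort_label=row["cohort_label"],
                    bmi=float(bmi_field) if bmi_field not in ("", "NA") else None,
                )
            )
        except (ParseError, ValueError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    variants = []
    for lineno, row in var_rows:
        try:
            variants.append(
                VariantRecord(
                    variant_id=row["variant_id"],
                    protein_pos=int(row["protein_pos"]),
                    func_class=row["func_class"],
                    notes=row.get("notes", ""),
                )
            )
        except (ParseError, ValueError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    genotypes = []
    for lineno, row in gt_rows:
        try:
            genotypes.append(
                GenotypeEntry(
                    individual_id=row["individual_id"],
                    variant_id=row["variant_id"],
                    allele_count=int(row["allele_count"]),
                )
            )
        except (ParseError, ValueError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
    return Cohort(individuals, variants, genotypes)


def read_variant_table(path: PathLike) -> Cohort:
    """Read a cohort from a stanza file or a directory of three TSVs.

    Raises :class:`ParseError` (naming the line) on malformed rows,
    :class:`ReferentialIntegrityError` on dangling genotype references, and
    :class:`DuplicateEntryError` on repeated ids or (individual, variant)
    pairs.  Individuals with no genotype entries are retained as
    non-carriers.
    """
    path = Path(path)
    if path.is_dir():
        parts = {}
        for name, cols in zip(_STANZAS, (_IND_COLS, _VAR_COLS, _GT_COLS)):
            f = path / f"{name}.tsv"
            if not f.exists():
                raise ParseError(f"missing table file {f}")
            lines = list(enumerate(f.read_text().splitlines(), start=1))
            parts[name] = _parse_rows(name, lines, cols)
        return _build_cohort(parts["individuals"], parts["variants"], parts["genotypes"])
    return _read_stanza_file(path)


def _read_stanza_file(path: Path) -> Cohort:
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    current: Optional[str] = None
    stanza_lines: dict[str, list[tuple[int, str]]] = {s: [] for s in _STANZAS}
    for lineno, line in enumerate(path.read_text().splitlines(), start=1):
        stripped = line.strip()
        if stripped.startswith("#[") and stripped.endswith("]"):
            name = stripped[2:-1]
            if name not in _STANZAS:
                raise ParseError(f"line {lineno}: unknown stanza {name!r}")
            current = name
            continue
        if not stripped or stripped.startswith("#"):
            continue
        if current is None:
            raise ParseError(f"line {lineno}: data before any stanza marker")
        stanza_lines[current].append((lineno, line))
    for name in _STANZAS:
        if not stanza_lines[name]:
            raise ParseError(f"stanza #[{name}] missing or empty in {path}")
    return _build_cohort(
        *(
            _parse_rows(name, stanza_lines[name], cols)
            for name, cols in zip(_STANZAS, (_IND_COLS, _VAR_COLS, _GT_COLS))
        )
    )


def _format_bmi(bmi: Optional[float]) -> str:
    if bmi is None:
        return ""
    return f"{bmi:.6g}"


def _stanza_texts(cohort: Cohort) -> dict[str, str]:
    ind = ["\t".join(_IND_COLS)]
    for i in cohort.individuals:
        ind.append(
            "\t".join(
                (i.individual_id, i.status.value, i.cohort_label.value,
                 _format_bmi(i.bmi))
            )
        )
    var = ["\t".join(_VAR_COLS + ("notes",))]
    for v in cohort.variants:
        var.append(
            "\t".join((v.variant_id, str(v.protein_pos), v.func_class.value, v.notes))
        )
    gt = ["\t".join(_GT_COLS)]
    for g in cohort.genotypes:
        gt.append("\t".join((g.individual_id, g.variant_id, str(g.allele_count))))
    return {
        "individuals": "\n".join(ind) + "\n",
        "variants": "\n".join(var) + "\n",
        "genotypes": "\n".join(gt) + "\n",
    }


def write_variant_table(cohort: Cohort, path: PathLike) -> Path:
    """Write a cohort: to three TSVs if ``path`` is/ends without ``.tsv``
    (treated as a directory), else to a single stanza file."""
    path = Path(path)
    texts = _stanza_texts(cohort)
    if path.suffix == ".tsv":
        with path.open("w") as fh:
            for name in _STANZAS:
                fh.write(f"#[{name}]\n")
                fh.write(texts[name])
        return path
    path.mkdir(parents=True, exist_ok=True)
    for name in _STANZAS:
        (path / f"{name}.tsv").write_text(texts[name])
    return path


# ---------------------------------------------------------------------------
# regions


def read_regions(path: PathLike) -> dict[str, RegionAnnotation]:
    """Read a regions TSV (region_name, start, end; 1-based inclusive)."""
    path = Path(path)
    if not path.exists():
        raise ParseError(f"no such file: {path}")
    regions: dict[str, RegionAnnotation] = {}
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"empty regions file {path}")
    cols = lines[0].split("\t")
    for required in ("region_name", "start", "end"):
        if required not in cols:
            raise ParseError(f"line 1: regions header missing {required!r}")
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = dict(zip(cols, line.split("\t")))
        try:
            region = RegionAnnotation(
                region_name=fields["region_name"],
                start=int(fields["start"]),
                end=int(fields["end"]),
            )
        except (KeyError, ValueError, ParseError) as exc:
            raise ParseError(f"line {lineno}: {exc}") from None
        if region.region_name in regions:
            raise ParseError(f"line {lineno}: duplicate region {region.region_name!r}")
        regions[region.region_name] = region
    return regions


def write_regions(regions: Iterable[RegionAnnotation], path: PathLike) -> Path:
    path = Path(path)
    lines = ["region_name\tstart\tend"]
    for r in regions:
        lines.append(f"{r.region_name}\t{r.start}\t{r.end}")
    path.write_text("\n".join(lines) + "\n")
    return path


# ---------------------------------------------------------------------------
# optional minimal VCF ingestion


def read_vcf(vcf_path: PathLike, individuals: Sequence[Individual]) -> Cohort:
    """Convert a single-gene VCF to the internal cohort model.

    Requirements: biallelic records only (multi-allelic sites are rejected),
    GT-typed samples, and an INFO key ``CSQ=func_class|protein_pos``.  The
    VCF sample names must exactly cover the supplied individuals, which carry
    the status/cohort/BMI information that VCF cannot.
    """
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover - environment-dependent
        raise ParseError("VCF support requires the cyvcf2 package") from exc

    vcf = VCF(str(vcf_path))
    ind_by_id = {i.individual_id: i for i in individuals}
    unknown = [s for s in vcf.samples if s not in ind_by_id]
    if unknown:
        raise ParseError(f"VCF samples with no individual record: {unknown[:5]}")
    variants: list[VariantRecord] = []
    genotypes: list[GenotypeEntry] = []
    for rec in vcf:
        if len(rec.ALT) != 1:
            raise ParseError(
                f"{rec.CHROM}:{rec.POS}: multi-allelic site (ALT={rec.ALT}); "
                "split the VCF before import"
            )
        csq = rec.INFO.get("CSQ")
        if csq is None or "|" not in str(csq):
            raise ParseError(
                f"{rec.CHROM}:{rec.POS}: missing CSQ=func_class|protein_pos INFO"
            )
        func_class, pos_str = str(csq).split("|", 1)
        vid = rec.ID or f"{rec.CHROM}:{rec.POS}:{rec.REF}:{rec.ALT[0]}"
        try:
            variants.append(
                VariantRecord(vid, int(pos_str), func_class.strip())
            )
        except (ValueError, ParseError) as exc:
            raise ParseError(f"{rec.CHROM}:{rec.POS}: {exc}") from None
        for sample, gt in zip(vcf.samples, rec.gt_types):
            # cyvcf2 gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
            if gt == 1:
                genotypes.append(GenotypeEntry(sample, vid, 1))
            elif gt == 3:
                genotypes.append(GenotypeEntry(sample, vid, 2))
    return Cohort(list(individuals), variants, genotypes)
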