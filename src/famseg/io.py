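"""Readers and writers: VCF, PED, annotated variant tables, reports.

VCF parsing is delegated to :mod:`cyvcf2`; multi-allelic records are split
into one biallelic record per alternate allele, with genotypes recoded
against that allele (any other allele index is treated as reference, the
``bcftools norm -m-`` convention).  Writing produces minimal VCF 4.2 with
``GENE`` / ``FUNC`` / ``MAF1KG`` INFO fields so that annotation survives a
round trip.

Indel representation: printed variant tables write pure deletions as
``GGA -> -`` while VCF requires an anchored base (``AGGA -> A``).
:func:`to_table_style` and :func:`to_vcf_style` convert between the two.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import is_dataclass, asdict
from pathlib import Path
from typing import Any, Iterable, Mapping, Optional, Sequence

from cyvcf2 import VCF

from .model import (
    AnnotatedVariant,
    CohortAnnotations,
    GenotypeCall,
    GenotypeTable,
    Individual,
    MISSING_CALL,
    Pedigree,
    PredictionProfile,
    Variant,
    chrom_sort_key,
)

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_pedigree",
    "read_variant_fixture",
    "write_report",
    "read_report",
    "to_table_style",
    "to_vcf_style",
]


class FixtureParseError(ValueError):
    """Raised for malformed variant-table fixtures, naming the row."""


# --------------------------------------------------------------------------
# indel representation normalizer
# --------------------------------------------------------------------------

def to_table_style(ref: str, alt: str, pos: int) -> tuple[str, str, int]:
    """Convert anchored VCF alleles to printed-table style.

    ``("AGGA", "A", 100) -> ("GGA", "-", 101)`` (deletion) and
    ``("A", "AG", 100) -> ("-", "G", 101)`` (insertion).  SNVs and
    length-matched alleles pass through unchanged.
    """
    if len(ref) == len(alt) or "-" in (ref, alt):
        return ref, alt, pos
    if len(ref) > len(alt) and ref.startswith(alt):
        return ref[len(alt):], "-", pos + len(alt)
    if len(alt) > len(ref) and alt.startswith(ref):
        return "-", alt[len(ref):], pos + len(ref)
    return ref, alt, pos


def to_vcf_style(ref: str, alt: str, pos: int, anchor: str = "N") -> tuple[str, str, int]:
    """Convert printed-table indel alleles back to anchored VCF style.

    The anchor is the reference base immediately preceding the indel; when
    the true base is unknown ``"N"`` is used (sufficient for round trips
    within this package, not for submission to external tools).
    """
    if ref == "-":
        return anchor, anchor + alt, pos - 1
    if alt == "-":
        return anchor + ref, anchor, pos - 1
    return ref, alt, pos


# --------------------------------------------------------------------------
# VCF
# --------------------------------------------------------------------------

def read_vcf(path: str | Path) -> GenotypeTable:
    """Read a VCF into a :class:`GenotypeTable`.

    One :class:`Variant` per alternate allele; sample order preserved.
    ``GENE``, ``FUNC`` and ``MAF1KG`` INFO fields populate the variant
    annotations when present.  ``./.`` genotypes become missing calls.
    """
    path = str(path)
    try:
        vcf = VCF(path)
    except Exception as exc:  # cyvcf2 raises bare Exceptions on bad headers
        raise ValueError(f"malformed VCF {path!r}: {exc}") from exc
    samples = list(vcf.samples)
    variants: list[Variant] = []
    calls: dict[tuple, GenotypeCall] = {}
    for record in vcf:
        if record.ALT is None or len(record.ALT) == 0:
            continue
        if "GT" not in (record.FORMAT or []):
            raise ValueError(
                f"record {record.CHROM}:{record.POS} in {path!r} has no GT field"
            )
        genotypes = record.genotypes  # [[a, b, phased], ...]
        gene = _info_str(record, "GENE")
        func = _info_str(record, "FUNC") or "other"
        maf = record.INFO.get("MAF1KG")
        maf = float(maf) if maf is not None else None
        for alt_index, alt in enumerate(record.ALT, start=1):
            variant = Variant(
                chrom=str(record.CHROM),
                pos=int(record.POS),
                ref=record.REF,
                alt=alt,
                gene=gene,
                dbsnp_id=record.ID,
                func_class=func,
                maf_1000g=maf,
            )
            variants.append(variant)
            for sample, g in zip(samples, genotypes):
                a, b = g[0], g[1]
                if a < 0 or b < 0:
                    calls[(variant.key, sample)] = MISSING_CALL
                else:
                    alleles = tuple(
                        alt if idx == alt_index else record.REF for idx in (a, b)
                    )
                    calls[(variant.key, sample)] = GenotypeCall(alleles)
    return GenotypeTable(variants, samples, calls)


def _info_str(record, field: str) -> str:
    value = record.INFO.get(field)
    return "" if value is None else str(value)


def write_vcf(table: GenotypeTable, path: str | Path) -> None:
    """Write a :class:`GenotypeTable` as sorted biallelic VCF 4.2.

    Variants using the printed-table ``"-"`` allele convention must be
    converted with :func:`to_vcf_style` first.
    """
    table = table.sorted()
    chroms = []
    for v in table.variants:
        if "-" in (v.ref, v.alt):
            raise ValueError(
                f"variant {v.label} uses table-style '-' alleles; "
                "convert with to_vcf_style() before writing VCF"
            )
        if v.chrom not in chroms:
            chroms.append(v.chrom)
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in sorted(chroms, key=chrom_sort_key)]
    lines += [
        '##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">',
        '##INFO=<ID=FUNC,Number=1,Type=String,Description="Functional class">',
        '##INFO=<ID=MAF1KG,Number=1,Type=Float,Description="1000 Genomes allele frequency">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(table.samples),
    ]
    for v in table.variants:
        info = []
        if v.gene:
            info.append(f"GENE={v.gene}")
        if v.func_class:
            info.append(f"FUNC={v.func_class}")
        if v.maf_1000g is not None:
            info.append(f"MAF1KG={v.maf_1000g:g}")
        fields = [
            v.chrom,
            str(v.pos),
            v.dbsnp_id or ".",
            v.ref,
            v.alt,
            ".",
            ".",
            ";".join(info) or ".",
            "GT",
        ]
        for sample in table.samples:
            call = table.call(v, sample)
            if call.is_missing:
                fields.append("./.")
            else:
                indices = sorted(_allele_index(a, v) for a in call.alleles)
                fields.append(f"{indices[0]}/{indices[1]}")
        lines.append("\t".join(fields))
    Path(path).write_text("\n".join(lines) + "\n")


def _allele_index(allele: str, variant: Variant) -> int:
    if allele == variant.ref:
        return 0
    if allele == variant.alt:
        return 1
    raise ValueError(
        f"allele {allele!r} at {variant.label} is neither ref nor alt"
    )


# --------------------------------------------------------------------------
# PED
# --------------------------------------------------------------------------

#: PED phenotype column -> affection state.
PED_AFFECTION_MAP = {"2": "cancer", "1": "unaffected", "0": "unknown", "-9": "unknown"}

PED_SEX_MAP = {"1": "male", "2": "female"}


def read_pedigree(
    path: str | Path,
    side_file: Optional[str | Path] = None,
) -> Pedigree:
    """Read a 6-column PED file into a :class:`Pedigree`.

    Columns: family, id, father, mother, sex, phenotype; ``0`` parent means
    no link.  Phenotype maps 2 -> cancer, 1 -> unaffected, 0/-9 -> unknown.
    PED cannot express polyp findings or sequencing roles; an optional
    tab-separated ``side_file`` with columns ``id``, ``affection``,
    ``phenotype_detail``, ``role`` overrides those fields per member.
    """
    individuals: list[Individual] = []
    parents: dict[str, tuple[Optional[str], Optional[str]]] = {}
    seen: set[str] = set()
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        cols = line.split()
        if len(cols) < 6:
            raise ValueError(f"{path}:{lineno}: PED rows need >= 6 columns, got {len(cols)}")
        _family, member, father, mother, sex, phenotype = cols[:6]
        if member in seen:
            raise ValueError(f"{path}:{lineno}: duplicate individual id {member!r}")
        seen.add(member)
        affection = PED_AFFECTION_MAP.get(phenotype)
        if affection is None:
            raise ValueError(f"{path}:{lineno}: unmapped phenotype code {phenotype!r}")
        individuals.append(
            Individual(id=member, sex=PED_SEX_MAP.get(sex), affection=affection)
        )
        links = (None if father == "0" else father, None if mother == "0" else mother)
        if links != (None, None):
            parents[member] = links
    overrides: dict[str, dict[str, str]] = {}
    if side_file is not None:
        for row in _read_tsv_rows(side_file, required=("id",)):
            overrides[row["id"]] = row
    if overrides:
        patched = []
        for ind in individuals:
            o = overrides.get(ind.id)
            if o:
                ind = Individual(
                    id=ind.id,
                    sex=ind.sex,
                    affection=o.get("affection") or ind.affection,
                    phenotype_detail=o.get("phenotype_detail") or ind.phenotype_detail,
                    role=o.get("role") or ind.role,
                )
            patched.append(ind)
        individuals = patched
    return Pedigree(individuals, parents)


def write_ped(pedigree: Pedigree, path: str | Path, family_id: str = "FAM1") -> None:
    """Write a pedigree as 6-column PED (inverse of the affection mapping)."""
    sex_code = {"male": "1", "female": "2"}
    aff_code = {"cancer": "2", "polyps": "2", "unaffected": "1", "unknown": "0"}
    lines = []
    for member in pedigree.members:
        ind = pedigree[member]
        father, mother = pedigree.parents.get(member, (None, None))
        lines.append(
            "\t".join(
                [
                    family_id,
                    member,
                    father or "0",
                    mother or "0",
                    sex_code.get(ind.sex or "", "0"),
                    aff_code[ind.affection],
                ]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


# --------------------------------------------------------------------------
# fixture table dialects
# --------------------------------------------------------------------------

_TABLE1_META = ("chrom", "pos", "ref", "alt", "gene", "dbsnp", "maf_1000g", "func_class")

_TABLE2_COLUMNS = (
    "chrom", "pos", "ref", "alt", "gene", "dbsnp", "maf_1000g",
    "freq_98_cases", "freq_249_controls", "func_class",
    "phylop", "sift", "polyphen2", "lrt", "mutation_taster", "flags",
)

_TABLE3_COLUMNS = (
    "chrom", "pos", "ref", "alt", "dbsnp", "gene", "func_class",
    "maf_1000g", "freq_249_controls", "freq_98_cases",
    "phylop", "sift", "polyphen2", "lrt", "mutation_taster",
    "fam_single_carrier", "fam_segregating", "fam_nonsegregating", "flags",
)


def read_variant_fixture(path: str | Path, dialect: str):
    """Read a tab-separated variant-table fixture.

    ``dialect="table1"`` returns a :class:`GenotypeTable` (segregation-test
    genotypes over named family members); ``"table2"`` a list of
    :class:`AnnotatedVariant` candidates with prediction profiles;
    ``"table3"`` a list of :class:`AnnotatedVariant` cohort records with
    frequencies and per-family segregation counts.
    """
    if dialect == "table1":
        return _read_table1(path)
    if dialect == "table2":
        return _read_annotated(path, _TABLE2_COLUMNS)
    if dialect == "table3":
        return _read_annotated(path, _TABLE3_COLUMNS)
    raise ValueError(f"unknown fixture dialect {dialect!r}")


def _read_tsv_rows(path: str | Path, required: Sequence[str] = ()) -> list[dict[str, str]]:
    with open(path, newline="") as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise FixtureParseError(f"{path}: empty file") from None
        missing = [c for c in required if c not in header]
        if missing:
            raise FixtureParseError(f"{path}: missing columns {missing}")
        rows = []
        for rownum, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise FixtureParseError(
                    f"{path}: row {rownum}: expected {len(header)} columns, got {len(row)}"
                )
            rows.append(dict(zip(header, row)))
    return rows


def _opt_float(text: str) -> Optional[float]:
    text = text.strip()
    if text in {"", "."}:
        return None
    value = float(text)
    if math.isnan(value):
        return None
    return value


def _opt_str(text: str) -> Optional[str]:
    text = text.strip()
    return None if text in {"", "."} else text


def _read_table1(path: str | Path) -> GenotypeTable:
    rows = _read_tsv_rows(path, required=_TABLE1_META)
    if not rows:
        raise FixtureParseError(f"{path}: no variant rows")
    samples = [c for c in rows[0] if c not in _TABLE1_META]
    variants: list[Variant] = []
    calls: dict[tuple, GenotypeCall] = {}
    for row in rows:
        variant = Variant(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            gene=row["gene"],
            dbsnp_id=_opt_str(row["dbsnp"]),
            func_class=row["func_class"],
            maf_1000g=_opt_float(row["maf_1000g"]),
        )
        variants.append(variant)
        for sample in samples:
            calls[(variant.key, sample)] = GenotypeCall.from_string(row[sample])
    return GenotypeTable(variants, samples, calls)


_FLAG_BY_CLASS = {
    "nonframeshift_deletion": "inframe_indel",
    "frameshift_deletion": "frameshift",
    "stopgain_SNV": "stopgain",
}


def _read_annotated(path: str | Path, columns: Sequence[str]) -> list[AnnotatedVariant]:
    rows = _read_tsv_rows(path, required=columns)
    records: list[AnnotatedVariant] = []
    for row in rows:
        func_class = row["func_class"]
        variant = Variant(
            chrom=row["chrom"],
            pos=int(row["pos"]),
            ref=row["ref"],
            alt=row["alt"],
            gene=row["gene"],
            dbsnp_id=_opt_str(row["dbsnp"]),
            func_class=func_class,
            maf_1000g=_opt_float(row["maf_1000g"]),
        )
        type_flags = frozenset(
            {_FLAG_BY_CLASS[func_class]} if func_class in _FLAG_BY_CLASS else set()
        )
        profile = PredictionProfile(
            phylop=_opt_str(row["phylop"]),
            sift=_opt_str(row["sift"]),
            polyphen2=_opt_str(row["polyphen2"]),
            lrt=_opt_str(row["lrt"]),
            mutation_taster=_opt_str(row["mutation_taster"]),
            variant_type_flags=type_flags,
        )
        cohort = CohortAnnotations(
            maf_1000g=_opt_float(row["maf_1000g"]),
            freq_249_controls=_opt_float(row["freq_249_controls"]),
            freq_98_cases=_opt_float(row["freq_98_cases"]),
            fam_single_carrier=int(row.get("fam_single_carrier") or 0),
            fam_segregating=int(row.get("fam_segregating") or 0),
            fam_nonsegregating=int(row.get("fam_nonsegregating") or 0),
        )
        flags = frozenset(f for f in (row.get("flags") or "").split(",") if f and f != ".")
        records.append(
            AnnotatedVariant(variant=variant, profile=profile, cohort=cohort, flags=flags)
        )
    return records


# --------------------------------------------------------------------------
# reports
# --------------------------------------------------------------------------

def _as_record(item: Any) -> dict[str, Any]:
    if is_dataclass(item) and not isinstance(item, type):
        return asdict(item)
    if isinstance(item, Variant):
        return {
            "chrom": item.chrom, "pos": item.pos, "ref": item.ref, "alt": item.alt,
            "gene": item.gene, "dbsnp": item.dbsnp_id or "",
            "func_class": item.func_class,
            "maf_1000g": "" if item.maf_1000g is None else item.maf_1000g,
        }
    if isinstance(item, Mapping):
        return dict(item)
    raise TypeError(f"cannot serialise record of type {type(item).__name__}")


def write_report(results: Iterable[Any], path: str | Path, format: str = "tsv") -> None:
    """Write pipeline results deterministically as TSV or JSON.

    Records carrying ``chrom`` / ``pos`` keys are sorted in natural
    chromosome order (1..22, X, Y) then by position; column order is the
    first-seen key order.  An empty result yields a header-only TSV or an
    empty JSON list.
    """
    records = [_as_record(r) for r in results]
    if records and all("chrom" in r and "pos" in r for r in records):
        records.sort(key=lambda r: (*chrom_sort_key(str(r["chrom"])), int(r["pos"])))
    columns: list[str] = []
    for record in records:
        for key in record:
            if key not in columns:
                columns.append(key)
    path = Path(path)
    if format == "tsv":
        with open(path, "w", newline="") as handle:
            writer = csv.writer(handle, delimiter="\t")
            writer.writerow(columns)
            for record in records:
                writer.writerow([_cell(record.get(c, "")) for c in columns])
    elif format == "json":
        path.write_text(json.dumps(records, indent=2, default=_json_default) + "\n")
    else:
        raise ValueError(f"unknown report format {format!r}")


def _cell(value: Any) -> str:
    if value is None:
        return ""
    if isinstance(value, (list, tuple, set, frozenset)):
        return ",".join(str(v) for v in value)
    return str(value)


def _json_default(value: Any):
    if isinstance(value, (set, frozenset)):
        return sorted(value)
    if isinstance(value, tuple):
        return list(value)
    raise TypeError(f"unserialisable {type(value).__name__}")


def read_report(path: str | Path) -> list[dict[str, Any]]:
    """Read back a JSON report written by :func:`write_report`."""
    return json.loads(Path(path).read_text())
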