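"""Variant and cohort table ingestion.

Parses HGVS protein notation, normalizes annotated variant tables (TSV or
VCF) and cohort tables (TSV) into in-memory records, applies the merging and
frequency conventions of the analysis (cis-adjacent substitutions merged with
the lower REVEL score; carriers defined by posterior dosage > 0.5; GnomAD
non-neuro popmax MAF with sample-frequency fallback), and joins carriers to
individuals.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ChangeKind",
    "ProteinChange",
    "VariantRecord",
    "CohortIndividual",
    "Cohort",
    "HgvsParseError",
    "parse_hgvs_p",
    "format_hgvs_p",
    "merge_cis_adjacent",
    "carrier_set",
    "effective_maf",
    "read_cohort_tsv",
    "read_variant_tsv",
    "read_variant_vcf",
    "write_variant_tsv",
]

AA1 = "ACDEFGHIKLMNPQRSTVWY"
AA3_TO_1 = {
    "Ala": "A", "Arg": "R", "Asn": "N", "Asp": "D", "Cys": "C", "Gln": "Q",
    "Glu": "E", "Gly": "G", "His": "H", "Ile": "I", "Leu": "L", "Lys": "K",
    "Met": "M", "Phe": "F", "Pro": "P", "Ser": "S", "Thr": "T", "Trp": "W",
    "Tyr": "Y", "Val": "V", "Ter": "*",
}
TERMINATOR = "*"


class ChangeKind(str, Enum):
    MISSENSE = "missense"
    NONSENSE = "nonsense"
    FRAMESHIFT = "frameshift"
    SPLICE = "splice"
    OTHER = "other"


class HgvsParseError(ValueError):
    """Raised for unparseable HGVS p. strings; carries the offending token."""

    def __init__(self, token: str, message: str = "cannot parse HGVS token"):
        self.token = token
        super().__init__(f"{message}: {token!r}")


@dataclass(frozen=True)
class ProteinChange:
    """A protein-level change parsed from HGVS p. notation.

    ``second_change`` holds the (ref, alt) of an adjacent second substitution
    at ``position + 1`` for merged in-cis double substitutions.
    """

    ref_aa: str
    position: int
    alt_aa: str
    kind: ChangeKind
    second_change: Optional[tuple[str, str]] = None

    def __post_init__(self) -> None:
        if self.position < 1:
            raise HgvsParseError(str(self.position), "residue position must be >= 1")
        if self.kind is ChangeKind.MISSENSE:
            if self.ref_aa == self.alt_aa or self.alt_aa not in AA1:
                raise HgvsParseError(
                    f"{self.ref_aa}{self.position}{self.alt_aa}",
                    "not a valid missense substitution",
                )
        if self.kind is ChangeKind.NONSENSE and self.alt_aa != TERMINATOR:
            raise HgvsParseError(self.alt_aa, "nonsense change must end in Ter")
        if self.second_change is not None and self.kind is not ChangeKind.MISSENSE:
            raise HgvsParseError(
                str(self.second_change), "double substitutions must be missense"
            )

    @property
    def positions(self) -> tuple[int, ...]:
        if self.second_change is None:
            return (self.position,)
        return (self.position, self.position + 1)

    def substitutions(self) -> list[tuple[str, int, str]]:
        """(ref, position, alt) for each amino-acid substitution."""
        subs = [(self.ref_aa, self.position, self.alt_aa)]
        if self.second_change is not None:
            ref2, alt2 = self.second_change
            subs.append((ref2, self.position + 1, alt2))
        return subs


_RE_SUB = re.compile(r"^([A-Z\*])(\d+)([A-Z\*])$")
_RE_SUB3 = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2}|\*)$")
_RE_FS = re.compile(r"^([A-Z])(\d+)([A-Z]?)fs(\*?\d*|Ter\d*)$")
_RE_FS3 = re.compile(r"^([A-Z][a-z]{2})(\d+)([A-Z][a-z]{2})?fs(\*?\d*|Ter\d*)$")
_RE_DELINS = re.compile(r"^([A-Z])(\d+)_([A-Z])(\d+)delins([A-Z]{2})$")


def _aa1(token: str, raw: str) -> str:
    if token in AA3_TO_1:
        return AA3_TO_1[token]
    if token in AA1 or token == "*" or token == "X":
        return TERMINATOR if token == "X" else token
    raise HgvsParseError(raw)


def parse_hgvs_p(text: str) -> ProteinChange:
    """Parse an HGVS protein change (one- or three-letter, bare or ``p.``).

    ``X``/``Ter``/``*`` terminators map to nonsense; an ``fs`` suffix maps to
    frameshift; ``A123_B124delinsXY`` encodes an adjacent double substitution.
    """
    if not isinstance(text, str) or not text.strip():
        raise HgvsParseError(str(text))
    raw = text.strip()
    body = raw[2:] if raw.startswith("p.") else raw
    body = body.strip("()")

    m = _RE_DELINS.match(body)
    if m:
        ref1, pos1, ref2, pos2, alts = m.groups()
        if int(pos2) != int(pos1) + 1:
            raise HgvsParseError(raw, "delins positions must be adjacent")
        return ProteinChange(
            ref_aa=ref1, position=int(pos1), alt_aa=alts[0],
            kind=ChangeKind.MISSENSE, second_change=(ref2, alts[1]),
        )
    for rx in (_RE_FS, _RE_FS3):
        m = rx.match(body)
        if m:
            ref = _aa1(m.group(1), raw)
            return ProteinChange(
                ref_aa=ref, position=int(m.group(2)), alt_aa=ref,
                kind=ChangeKind.FRAMESHIFT,
            )
    for rx in (_RE_SUB, _RE_SUB3):
        m = rx.match(body)
        if m:
            ref = _aa1(m.group(1), raw)
            alt = _aa1(m.group(3), raw)
            if ref not in AA1:
                raise HgvsParseError(raw, "invalid reference amino acid")
            if alt == TERMINATOR:
                return ProteinChange(ref, int(m.group(2)), TERMINATOR,
                                     ChangeKind.NONSENSE)
            return ProteinChange(ref, int(m.group(2)), alt, ChangeKind.MISSENSE)
    raise HgvsParseError(raw)


def format_hgvs_p(change: ProteinChange) -> str:
    """Canonical one-letter HGVS p. string; inverse of :func:`parse_hgvs_p`."""
    if change.second_change is not None:
        ref2, alt2 = change.second_change
        return (
            f"p.{change.ref_aa}{change.position}_{ref2}{change.position + 1}"
            f"delins{change.alt_aa}{alt2}"
        )
    if change.kind is ChangeKind.FRAMESHIFT:
        return f"p.{change.ref_aa}{change.position}fs"
    if change.kind is ChangeKind.NONSENSE:
        return f"p.{change.ref_aa}{change.position}*"
    return f"p.{change.ref_aa}{change.position}{change.alt_aa}"


@dataclass
class VariantRecord:
    """One annotated coding variant with its per-individual carrier dosages."""

    variant_id: str
    hgvs_p: Optional[ProteinChange] = None
    consequence: Optional[str] = None  # e.g. "splice_donor_variant"
    exon: Optional[int] = None
    revel: Optional[float] = None
    loftee_flag: int = 0
    splice_score: Optional[float] = None
    gnomad_nonneuro_popmax_maf: Optional[float] = None
    carriers: dict[str, float] = field(default_factory=dict)
    flags: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.revel is not None and not (0.0 <= self.revel <= 1.0):
            raise ValueError(f"REVEL score out of [0,1]: {self.revel}")
        for ind, dosage in self.carriers.items():
            if not (0.0 <= dosage <= 2.0):
                raise ValueError(f"dosage for {ind} out of [0,2]: {dosage}")

    @property
    def change_kind(self) -> ChangeKind:
        if self.hgvs_p is not None:
            return self.hgvs_p.kind
        c = (self.consequence or "").lower()
        if "splice" in c:
            return ChangeKind.SPLICE
        if "frameshift" in c:
            return ChangeKind.FRAMESHIFT
        if "stop_gained" in c or "nonsense" in c:
            return ChangeKind.NONSENSE
        return ChangeKind.OTHER


@dataclass
class CohortIndividual:
    """One case or control with onset/screening age and covariates."""

    id: str
    status: str  # "case" | "control"
    aao_or_age: float
    apoe_e4_count: Optional[int] = None
    apoe_e2_count: Optional[int] = None
    pcs: Optional[tuple[float, ...]] = None
    cohort_label: Optional[str] = None

    def __post_init__(self) -> None:
        if self.status not in ("case", "control"):
            raise ValueError(f"status must be case/control, got {self.status!r}")
        if not self.aao_or_age > 0:
            raise ValueError(f"age must be positive, got {self.aao_or_age}")
        for attr in ("apoe_e4_count", "apoe_e2_count"):
            v = getattr(self, attr)
            if v is not None and v not in (0, 1, 2):
                raise ValueError(f"{attr} must be 0/1/2 or missing, got {v}")


#: Exclusion region: an exon number or an inclusive residue range.
ExclusionRegion = tuple  # ("exon", n) | ("residues", start, end)

DEFAULT_EXCLUSIONS: list[ExclusionRegion] = [("exon", 1), ("residues", 1, 95)]


@dataclass
class Cohort:
    """Individuals joined to the variant table they were genotyped for."""

    individuals: list[CohortIndividual]
    variants: list[VariantRecord] = field(default_factory=list)
    exclusion_regions: list[ExclusionRegion] = field(
        default_factory=lambda: list(DEFAULT_EXCLUSIONS)
    )

    def __post_init__(self) -> None:
        ids = {ind.id for ind in self.individuals}
        if len(ids) != len(self.individuals):
            raise ValueError("duplicate individual ids in cohort")
        for rec in self.variants:
            unknown = set(rec.carriers) - ids
            if unknown:
                raise ValueError(
                    f"variant {rec.variant_id} has carriers not in the cohort: "
                    f"{sorted(unknown)[:5]}"
                )
        self._by_id = {ind.id: ind for ind in self.individuals}

    def __len__(self) -> int:
        return len(self.individuals)

    def individual(self, ind_id: str) -> CohortIndividual:
        return self._by_id[ind_id]

    @property
    def cases(self) -> list[CohortIndividual]:
        return [i for i in self.individuals if i.status == "case"]

    @property
    def controls(self) -> list[CohortIndividual]:
        return [i for i in self.individuals if i.status == "control"]

    def is_excluded(self, record: VariantRecord) -> bool:
        """True if the variant falls in a configured exclusion region."""
        for region in self.exclusion_regions:
            if region[0] == "exon":
                if record.exon is not None and record.exon == region[1]:
                    return True
            elif region[0] == "residues":
                if record.hgvs_p is not None:
                    lo, hi = region[1], region[2]
                    if any(lo <= p <= hi for p in record.hgvs_p.positions):
                        return True
        return False


# -- operations ----------------------------------------------------------


def carrier_set(record: VariantRecord, dosage_threshold: float = 0.5) -> set[str]:
    """Individuals with posterior dosage strictly above the threshold."""
    if not (0.0 < dosage_threshold < 2.0):
        raise ValueError("dosage threshold must lie in (0, 2)")
    return {ind for ind, d in record.carriers.items() if d > dosage_threshold}


def effective_maf(
    record: VariantRecord,
    cohort: Cohort,
    dosage_threshold: float = 0.5,
    allele_based: bool = False,
) -> tuple[float, str]:
    """(MAF, source) — GnomAD non-neuro popmax when available, else sample.

    The sample fallback is the carrier frequency |carriers| / N individuals
    (the convention under which 21 carriers of 40,852 individuals crosses the
    0.05% rare threshold); set ``allele_based`` for alleles / 2N instead.
    """
    if len(cohort) == 0:
        raise ValueError("cohort is empty")
    if record.gnomad_nonneuro_popmax_maf is not None:
        return float(record.gnomad_nonneuro_popmax_maf), "gnomad"
    n_carriers = len(carrier_set(record, dosage_threshold))
    denom = 2 * len(cohort) if allele_based else len(cohort)
    return n_carriers / denom, "sample"


def _genomic_pos(variant_id: str) -> Optional[int]:
    parts = variant_id.split(":")
    try:
        return int(parts[1])
    except (IndexError, ValueError):
        return None


def merge_cis_adjacent(
    records: Sequence[VariantRecord],
    phase_info: Optional[Mapping[frozenset, str]] = None,
    dosage_threshold: float = 0.5,
) -> list[VariantRecord]:
    """Merge juxtaposed in-cis missense pairs into single double substitutions.

    Two records are juxtaposed when their protein changes are single missense
    substitutions at adjacent residues.  A pair is merged only when phase_info
    marks it ``cis`` and both records have identical carrier sets; the merged
    record's REVEL is the minimum of the pair (conservative), its carriers the
    per-individual minimum dosage, and its GnomAD MAF the pair minimum.
    Pairs of unknown phase are left unmerged with a ``phase_unknown`` flag.
    """
    phase_info = dict(phase_info or {})
    out: list[VariantRecord] = []
    used: set[int] = set()
    recs = list(records)
    for i, a in enumerate(recs):
        if i in used:
            continue
        merged = None
        for j in range(i + 1, len(recs)):
            if j in used:
                continue
            b = recs[j]
            if not _juxtaposed(a, b):
                continue
            first, second = (a, b) if _order(a, b) else (b, a)
            phase = phase_info.get(frozenset({a.variant_id, b.variant_id}), "unknown")
            same_carriers = carrier_set(a, dosage_threshold) == carrier_set(
                b, dosage_threshold
            )
            if phase == "cis" and same_carriers:
                merged = _merge_pair(first, second)
                used.add(j)
                break
            if phase == "unknown":
                a.flags.add("phase_unknown")
                b.flags.add("phase_unknown")
        out.append(merged if merged is not None else a)
        used.add(i)
    return out


def _juxtaposed(a: VariantRecord, b: VariantRecord) -> bool:
    pa, pb = a.hgvs_p, b.hgvs_p
    if pa is None or pb is None:
        return False
    if pa.kind is not ChangeKind.MISSENSE or pb.kind is not ChangeKind.MISSENSE:
        return False
    if pa.second_change is not None or pb.second_change is not None:
        return False
    return abs(pa.position - pb.position) == 1


def _order(a: VariantRecord, b: VariantRecord) -> bool:
    return a.hgvs_p.position < b.hgvs_p.position


def _merge_pair(first: VariantRecord, second: VariantRecord) -> VariantRecord:
    p1, p2 = first.hgvs_p, second.hgvs_p
    change = ProteinChange(
        ref_aa=p1.ref_aa, position=p1.position, alt_aa=p1.alt_aa,
        kind=ChangeKind.MISSENSE, second_change=(p2.ref_aa, p2.alt_aa),
    )
    revels = [r for r in (first.revel, second.revel) if r is not None]
    mafs = [
        m
        for m in (first.gnomad_nonneuro_popmax_maf, second.gnomad_nonneuro_popmax_maf)
        if m is not None
    ]
    carriers = {
        ind: min(first.carriers[ind], second.carriers[ind])
        for ind in set(first.carriers) & set(second.carriers)
    }
    return VariantRecord(
        variant_id=f"{first.variant_id};{second.variant_id}",
        hgvs_p=change,
        consequence="missense_variant",
        exon=first.exon,
        revel=min(revels) if revels else None,
        loftee_flag=0,
        gnomad_nonneuro_popmax_maf=min(mafs) if mafs else None,
        carriers=carriers,
        flags={"merged_cis"} | first.flags | second.flags,
    )


# -- table I/O -----------------------------------------------------------

COHORT_COLUMNS = ["id", "status", "aao_or_age", "apoe_e4", "apoe_e2",
                  "pc1", "pc2", "pc3", "pc4", "pc5", "pc6", "cohort"]


def _coerce_age(value) -> float:
    """Ages annotated '> 89' are stored as 90."""
    if isinstance(value, str):
        stripped = value.replace(" ", "")
        if stripped in (">89", "&gt;89"):
            return 90.0
        value = float(stripped)
    return float(value)


def read_cohort_tsv(path) -> list[CohortIndividual]:
    """Read a cohort table (columns: id, status, aao_or_age, apoe_e4,
    apoe_e2, pc1..pc6, cohort; missing values blank or NA)."""
    df = pd.read_csv(path, sep="\t", dtype={"id": str, "aao_or_age": str})
    individuals = []
    for row in df.itertuples(index=False):
        pcs = tuple(
            float(getattr(row, f"pc{k}")) for k in range(1, 7)
            if hasattr(row, f"pc{k}") and pd.notna(getattr(row, f"pc{k}"))
        )
        individuals.append(
            CohortIndividual(
                id=str(row.id),
                status=str(row.status),
                aao_or_age=_coerce_age(row.aao_or_age),
                apoe_e4_count=_opt_int(getattr(row, "apoe_e4", None)),
                apoe_e2_count=_opt_int(getattr(row, "apoe_e2", None)),
                pcs=pcs if len(pcs) == 6 else None,
                cohort_label=_opt_str(getattr(row, "cohort", None)),
            )
        )
    return individuals


def _opt_int(v) -> Optional[int]:
    return None if v is None or (isinstance(v, float) and np.isnan(v)) or pd.isna(v) else int(v)


def _opt_float(v) -> Optional[float]:
    return None if v is None or pd.isna(v) else float(v)


def _opt_str(v) -> Optional[str]:
    return None if v is None or pd.isna(v) else str(v)


VARIANT_COLUMNS = [
    "variant_id", "hgvs_p", "consequence", "exon", "revel", "loftee",
    "splice_ai", "gnomad_nonneuro_popmax_maf", "carriers",
]


def read_variant_tsv(path) -> list[VariantRecord]:
    """Read a flat variant table.  ``carriers`` is ``id:dosage`` pairs joined
    by commas (empty for none)."""
    df = pd.read_csv(path, sep="\t", dtype={"variant_id": str, "hgvs_p": str,
                                            "carriers": str})
    records = []
    for row in df.itertuples(index=False):
        hgvs = _opt_str(getattr(row, "hgvs_p", None))
        carriers_str = _opt_str(getattr(row, "carriers", None))
        carriers = {}
        if carriers_str:
            for tok in carriers_str.split(","):
                ind, dosage = tok.split(":")
                carriers[ind] = float(dosage)
        records.append(
            VariantRecord(
                variant_id=str(row.variant_id),
                hgvs_p=parse_hgvs_p(hgvs) if hgvs else None,
                consequence=_opt_str(getattr(row, "consequence", None)),
                exon=_opt_int(getattr(row, "exon", None)),
                revel=_opt_float(getattr(row, "revel", None)),
                loftee_flag=int(_opt_int(getattr(row, "loftee", 0)) or 0),
                splice_score=_opt_float(getattr(row, "splice_ai", None)),
                gnomad_nonneuro_popmax_maf=_opt_float(
                    getattr(row, "gnomad_nonneuro_popmax_maf", None)
                ),
                carriers=carriers,
            )
        )
    return records


def write_variant_tsv(records: Iterable[VariantRecord], path) -> None:
    rows = []
    for rec in records:
        rows.append({
            "variant_id": rec.variant_id,
            "hgvs_p": format_hgvs_p(rec.hgvs_p) if rec.hgvs_p else "",
            "consequence": rec.consequence or "",
            "exon": rec.exon if rec.exon is not None else "",
            "revel": rec.revel if rec.revel is not None else "",
            "loftee": rec.loftee_flag,
            "splice_ai": rec.splice_score if rec.splice_score is not None else "",
            "gnomad_nonneuro_popmax_maf": (
                rec.gnomad_nonneuro_popmax_maf
                if rec.gnomad_nonneuro_popmax_maf is not None else ""
            ),
            "carriers": ",".join(f"{i}:{d:g}" for i, d in sorted(rec.carriers.items())),
        })
    pd.DataFrame(rows, columns=VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_variant_vcf(path) -> list[VariantRecord]:
    """Read variants from a VCF (GRCh37) with annotations in INFO fields.

    Recognized INFO keys: HGVSP, CSQ_CONSEQUENCE (or Consequence), EXON,
    REVEL, LOFTEE, SPLICEAI, GNOMAD_NN_POPMAX.  Per-sample dosages are read
    from the DS FORMAT field when present, else from hard genotypes.
    """
    import pysam

    records = []
    with pysam.VariantFile(str(path)) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            for alt in rec.alts or ():
                vid = f"{rec.chrom}:{rec.pos}:{rec.ref}>{alt}"
                info = dict(rec.info)
                hgvs = info.get("HGVSP")
                if isinstance(hgvs, tuple):
                    hgvs = hgvs[0]
                consequence = info.get("CSQ_CONSEQUENCE") or info.get("Consequence")
                if isinstance(consequence, tuple):
                    consequence = consequence[0]
                carriers = {}
                for sample in samples:
                    fmt = rec.samples[sample]
                    if "DS" in fmt and fmt["DS"] is not None:
                        dosage = float(fmt["DS"])
                    else:
                        gt = fmt.get("GT") or ()
                        dosage = float(sum(1 for g in gt if g not in (None, 0)))
                    if dosage > 0:
                        carriers[sample] = dosage
                records.append(
                    VariantRecord(
                        variant_id=vid,
                        hgvs_p=parse_hgvs_p(str(hgvs)) if hgvs else None,
                        consequence=str(consequence) if consequence else None,
                        exon=_info_int(info.get("EXON")),
                        revel=_info_float(info.get("REVEL")),
                        loftee_flag=int(_info_int(info.get("LOFTEE")) or 0),
                        splice_score=_info_float(info.get("SPLICEAI")),
                        gnomad_nonneuro_popmax_maf=_info_float(
                            info.get("GNOMAD_NN_POPMAX")
                        ),
                        carriers=carriers,
                    )
                )
    return records


def _info_int(v) -> Optional[int]:
    if isinstance(v, tuple):
        v = v[0]
    return None if v is None else int(v)


def _info_float(v) -> Optional[float]:
    if isinstance(v, tuple):
        v = v[0]
    return None if v is None else float(v)
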