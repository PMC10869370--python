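"""Family carrier counts and serrated polyposis syndrome (SPS) criteria.

The family/phenotype table is a long CSV: one row per person-event, where
an event is a cancer diagnosis, a polyp finding, or ``none`` for people
with no recorded events.  Person-level columns (sex, genotypes, age at
last contact) repeat on every row of the person.

Carrier summaries treat obligate carriers (inferred from pedigree
structure, not tested directly) as carriers.  Cancer-affected means at
least one cancer diagnosis row; polyps are never malignancies.

The WHO 2019 diagnostic criteria for SPS, evaluated cumulatively over a
person's polyp history:

1. five or more serrated polyps proximal to the rectum, all at least
   5 mm, at least two of them at least 10 mm; or
2. more than twenty serrated polyps of any size in the large bowel, at
   least five of them proximal to the rectum.

Serrated histologies are hyperplastic polyps, sessile serrated lesions
(SSL) and traditional serrated adenomas (TSA).  Size ranges such as
"6-8 mm" are judged against thresholds by a configurable rule
(lower bound by default, the conservative choice).
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Sequence

import pandas as pd

SCHEMA_COLUMNS = [
    "person_id", "sex", "genotype_brca1", "genotype_rnf43",
    "age_last_contact", "event_type", "age", "tumor_type", "location",
    "histology", "size_min_mm", "size_max_mm", "count", "background_lesion",
]


class Genotype(str, enum.Enum):
    CARRIER = "carrier"
    OBLIGATE_CARRIER = "obligate_carrier"
    WILDTYPE = "wildtype"
    UNKNOWN = "unknown"
    NOT_TESTED = "not_tested"

    @property
    def is_carrier(self) -> bool:
        return self in (Genotype.CARRIER, Genotype.OBLIGATE_CARRIER)


class Histology(str, enum.Enum):
    HYPERPLASTIC = "hyperplastic"
    SSL = "SSL"
    TSA = "TSA"
    TUBULAR_ADENOMA = "tubular_adenoma"
    ADENOMATOUS = "adenomatous"
    OTHER = "other"


SERRATED_HISTOLOGIES = frozenset(
    {Histology.HYPERPLASTIC, Histology.SSL, Histology.TSA}
)

_GENOTYPE_TOKENS = {
    "carrier": Genotype.CARRIER,
    "obligate_carrier": Genotype.OBLIGATE_CARRIER,
    "obligate carrier": Genotype.OBLIGATE_CARRIER,
    "wildtype": Genotype.WILDTYPE,
    "wt": Genotype.WILDTYPE,
    "unknown": Genotype.UNKNOWN,
    "not_tested": Genotype.NOT_TESTED,
    "not tested": Genotype.NOT_TESTED,
}

_HISTOLOGY_TOKENS = {
    "hyperplastic": Histology.HYPERPLASTIC,
    "ssl": Histology.SSL,
    "sessile_serrated_lesion": Histology.SSL,
    "tsa": Histology.TSA,
    "traditional_serrated_adenoma": Histology.TSA,
    "tubular_adenoma": Histology.TUBULAR_ADENOMA,
    "adenomatous": Histology.ADENOMATOUS,
    "other": Histology.OTHER,
}


@dataclass
class CancerDiagnosis:
    age: float | None
    tumor_type: str
    location: str = ""
    histology: str = ""

    @property
    def is_crc(self) -> bool:
        return self.tumor_type.strip().upper() == "CRC"


@dataclass
class PolypRecord:
    age: float | None
    location: str
    histology: Histology
    size_min_mm: float | None = None
    size_max_mm: float | None = None
    count: int = 1
    background_lesion: bool = False

    def __post_init__(self) -> None:
        if (
            self.size_min_mm is not None
            and self.size_max_mm is not None
            and self.size_min_mm > self.size_max_mm
        ):
            raise ValueError("size_min_mm must be <= size_max_mm")
        if self.count < 1:
            raise ValueError("count must be >= 1")

    @property
    def is_serrated(self) -> bool:
        return self.histology in SERRATED_HISTOLOGIES


@dataclass
class FamilyMember:
    person_id: str
    sex: str
    genotype_brca1: Genotype
    genotype_rnf43: Genotype
    diagnoses: list[CancerDiagnosis] = field(default_factory=list)
    polyps: list[PolypRecord] = field(default_factory=list)
    age_last_contact: float | None = None

    @property
    def cancer_affected(self) -> bool:
        return len(self.diagnoses) > 0

    @property
    def crc_affected(self) -> bool:
        return any(d.is_crc for d in self.diagnoses)


def packaged_family_table() -> Path:
    """Path of the family/phenotype table shipped with the package."""
    return Path(resources.files("digenicloh") / "data" / "table1.csv")


def _parse_genotype(token, row_no: int, person: str) -> Genotype:
    s = str(token).strip().lower().replace("-", "_")
    if s in _GENOTYPE_TOKENS:
        return _GENOTYPE_TOKENS[s]
    raise ValueError(
        f"row {row_no} (person {person}): unknown genotype token {token!r}; "
        f"expected one of {sorted(set(_GENOTYPE_TOKENS))}"
    )


def _parse_histology(token, row_no: int, person: str) -> Histology:
    s = str(token).strip().lower().replace(" ", "_")
    if s in _HISTOLOGY_TOKENS:
        return _HISTOLOGY_TOKENS[s]
    raise ValueError(
        f"row {row_no} (person {person}): unknown histology token {token!r}"
    )


def _opt_float(v) -> float | None:
    if v is None or (isinstance(v, float) and math.isnan(v)) or str(v) == "":
        return None
    return float(v)


def load_family_table(path: str | Path | None = None) -> list[FamilyMember]:
    """Load a family/phenotype CSV into members (packaged table by default)."""
    if path is None:
        path = packaged_family_table()
    try:
        df = pd.read_csv(path, dtype={"person_id": str}, keep_default_na=True)
    except pd.errors.EmptyDataError:
        return []
    if df.empty:
        return []
    missing = set(SCHEMA_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    def _str(v) -> str:
        return "" if pd.isna(v) else str(v)

    members: dict[str, FamilyMember] = {}
    for row_no, row in enumerate(df.to_dict("records"), start=2):
        pid = str(row["person_id"])
        if pid not in members:
            members[pid] = FamilyMember(
                person_id=pid,
                sex=_str(row["sex"]),
                genotype_brca1=_parse_genotype(
                    row["genotype_brca1"], row_no, pid
                ),
                genotype_rnf43=_parse_genotype(
                    row["genotype_rnf43"], row_no, pid
                ),
                age_last_contact=_opt_float(row["age_last_contact"]),
            )
        m = members[pid]
        etype = _str(row["event_type"]).strip().lower()
        if etype == "none":
            continue
        if etype == "cancer":
            m.diagnoses.append(
                CancerDiagnosis(
                    age=_opt_float(row["age"]),
                    tumor_type=_str(row["tumor_type"]).strip(),
                    location=_str(row["location"]),
                    histology=_str(row["histology"]),
                )
            )
        elif etype == "polyp":
            count = row["count"]
            m.polyps.append(
                PolypRecord(
                    age=_opt_float(row["age"]),
                    location=_str(row["location"]),
                    histology=_parse_histology(row["histology"], row_no, pid),
                    size_min_mm=_opt_float(row["size_min_mm"]),
                    size_max_mm=_opt_float(row["size_max_mm"]),
                    count=1 if pd.isna(count) else int(count),
                    background_lesion=_str(row["background_lesion"])
                    .strip()
                    .lower()
                    in ("true", "1", "yes"),
                )
            )
        else:
            raise ValueError(
                f"row {row_no} (person {pid}): unknown event_type {etype!r}"
            )
    return list(members.values())


@dataclass
class CarrierSummary:
    brca1_carriers: int
    rnf43_carriers: int
    dual_carriers: int
    dual_carriers_cancer_affected: int
    dual_carriers_crc: int

    def as_dict(self) -> dict[str, int]:
        return {
            "brca1_carriers": self.brca1_carriers,
            "rnf43_carriers": self.rnf43_carriers,
            "dual_carriers": self.dual_carriers,
            "dual_carriers_cancer_affected": self.dual_carriers_cancer_affected,
            "dual_carriers_crc": self.dual_carriers_crc,
        }


def carrier_summary(members: Sequence[FamilyMember]) -> CarrierSummary:
    """Carrier and segregation counts; obligate carriers count as carriers."""
    brca1 = [m for m in members if m.genotype_brca1.is_carrier]
    rnf43 = [m for m in members if m.genotype_rnf43.is_carrier]
    dual = [m for m in brca1 if m.genotype_rnf43.is_carrier]
    return CarrierSummary(
        brca1_carriers=len(brca1),
        rnf43_carriers=len(rnf43),
        dual_carriers=len(dual),
        dual_carriers_cancer_affected=sum(m.cancer_affected for m in dual),
        dual_carriers_crc=sum(m.crc_affected for m in dual),
    )


@dataclass
class SPSCriteriaConfig:
    """How the WHO 2019 polyp criteria are judged.

    ``rectum_labels`` name the segments NOT proximal to the rectum;
    everything else (including generic "colon") counts as proximal.
    ``size_rule`` picks which end of a reported size range is compared
    against the 5 mm / 10 mm thresholds; unknown sizes never qualify.
    """

    rectum_labels: frozenset[str] = frozenset({"rectum"})
    size_rule: str = "lower_bound"
    include_lesion_background_ssl: bool = True

    def __post_init__(self) -> None:
        if self.size_rule not in ("lower_bound", "upper_bound", "midpoint"):
            raise ValueError(f"invalid size_rule {self.size_rule!r}")
        self.rectum_labels = frozenset(
            s.strip().lower() for s in self.rectum_labels
        )

    def is_proximal(self, location: str) -> bool:
        loc = location.strip().lower()
        return bool(loc) and loc not in self.rectum_labels

    def effective_size(self, p: PolypRecord) -> float | None:
        lo, hi = p.size_min_mm, p.size_max_mm
        if lo is None and hi is None:
            return None
        lo = lo if lo is not None else hi
        hi = hi if hi is not None else lo
        if self.size_rule == "lower_bound":
            return lo
        if self.size_rule == "upper_bound":
            return hi
        return (lo + hi) / 2.0


@dataclass
class SPSResult:
    meets_criterion_1: bool
    meets_criterion_2: bool

    @property
    def meets_any(self) -> bool:
        return self.meets_criterion_1 or self.meets_criterion_2

    def as_dict(self) -> dict[str, bool]:
        return {
            "meets_criterion_1": self.meets_criterion_1,
            "meets_criterion_2": self.meets_criterion_2,
            "meets_any": self.meets_any,
        }


def sps_who2019(
    member: FamilyMember, cfg: SPSCriteriaConfig | None = None
) -> SPSResult:
    """Evaluate the WHO 2019 SPS criteria over the cumulative polyp history."""
    cfg = cfg or SPSCriteriaConfig()
    serrated = [
        p for p in member.polyps
        if p.is_serrated
        and (cfg.include_lesion_background_ssl or not p.background_lesion)
    ]
    proximal = [p for p in serrated if cfg.is_proximal(p.location)]

    def n_with_size_at_least(polyps: list[PolypRecord], mm: float) -> int:
        total = 0
        for p in polyps:
            size = cfg.effective_size(p)
            if size is not None and size >= mm:
                total += p.count
        return total

    n_prox_ge5 = n_with_size_at_least(proximal, 5.0)
    n_prox_ge10 = n_with_size_at_least(proximal, 10.0)
    criterion_1 = n_prox_ge5 >= 5 and n_prox_ge10 >= 2

    n_serrated_total = sum(p.count for p in serrated)
    n_proximal_total = sum(p.count for p in proximal)
    criterion_2 = n_serrated_total > 20 and n_proximal_total >= 5

    return SPSResult(criterion_1, criterion_2)
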