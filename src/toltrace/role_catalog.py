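"""Map Pfam domain hits on a gene to the fixed functional roles of the
Tol-Pal / Ton machinery.

The catalog ships as an editable TSV (``data/role_catalog.tsv``) so new
accessions can be added without code changes.  Two roles are composite:

* ``tolB`` requires the beta-propeller hit (PF07676); a propeller-only gene
  is reported as ``tolB_like`` and an N-domain-only gene as ``tolB_nterm``,
  neither of which counts toward the minimal tol-pal complement.
* ``tbdt`` requires both the barrel (PF00593) and the plug (PF07715) by
  default; barrel-only genes are ambiguous and reported as ``tbdt_barrel``
  unless ``require_plug=False``.

Genes whose passing hits map to several role families are flagged ambiguous
and resolved deterministically: the family of the best-bitscore hit wins,
ties broken by lexicographic Pfam accession.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional, Sequence

from .formats_io import DomainHit, SecondaryStructureProfile

ROLES = (
    "motor_pentamer", "motor_dimer", "transducer", "tolB", "tolB_like",
    "tolB_nterm", "pal", "cpoB_tpr", "ybgC", "tbdt", "tbdt_barrel",
    "tbdt_plug", "none",
)

#: roles that count toward the minimal tol-pal complement
COMPLEMENT_ROLES = frozenset(
    {"motor_pentamer", "motor_dimer", "transducer", "tolB", "pal"}
)


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class RoleAssignment:
    gene_id: str
    role: str
    supporting_hits: tuple[DomainHit, ...] = ()
    ambiguous: bool = False

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise ValueError(f"unknown role {self.role!r}")
        if (self.role == "none") != (len(self.supporting_hits) == 0):
            raise ValueError("role 'none' iff supporting_hits empty")


def load_role_catalog(path: Optional[str | Path] = None) -> dict[str, str]:
    """pfam_acc -> base role mapping, from the shipped or a user TSV."""
    if path is None:
        src = resources.files("toltrace").joinpath("data/role_catalog.tsv")
        text = src.read_text()
    else:
        text = Path(path).read_text()
    catalog: dict[str, str] = {}
    for row in csv.DictReader(text.splitlines(), delimiter="\t"):
        catalog[row["pfam_acc"]] = row["role"]
    return catalog


# base roles that fold into one composite family for conflict purposes
_FAMILY = {
    "tolB_propeller": "tolB", "tolB_nterm": "tolB",
    "tbdt_barrel": "tbdt", "tbdt_plug": "tbdt",
}


def _family_of(base_role: str) -> str:
    return _FAMILY.get(base_role, base_role)


def _resolve_family(base_roles: set[str], require_plug: bool) -> str:
    """Collapse the base roles of one family into the reported role."""
    if base_roles <= {"tolB_propeller", "tolB_nterm"}:
        if "tolB_propeller" in base_roles and "tolB_nterm" in base_roles:
            return "tolB"
        if "tolB_propeller" in base_roles:
            return "tolB_like"
        return "tolB_nterm"
    if base_roles <= {"tbdt_barrel", "tbdt_plug"}:
        if {"tbdt_barrel", "tbdt_plug"} <= base_roles:
            return "tbdt"
        if base_roles == {"tbdt_barrel"}:
            return "tbdt" if not require_plug else "tbdt_barrel"
        return "tbdt_plug"
    assert len(base_roles) == 1
    return next(iter(base_roles))


def assign_roles(
    hits: Sequence[DomainHit],
    evalue_max: float = 1e-5,
    catalog: Optional[dict[str, str]] = None,
    require_plug: bool = True,
) -> list[RoleAssignment]:
    """Assign exactly one functional role per gene from its passing hits.

    A pure function of (hits, evalue_max): input order never changes the
    output, which is sorted by gene_id.  Unknown Pfam accessions map to no
    role; a gene whose passing hits span several role families is flagged
    ambiguous and resolved by best bitscore (tie: lexicographic accession).
    """
    if evalue_max <= 0:
        raise ConfigError(f"evalue_max must be > 0, got {evalue_max}")
    catalog = catalog if catalog is not None else load_role_catalog()

    by_gene: dict[str, list[DomainHit]] = {}
    for h in hits:
        by_gene.setdefault(h.gene_id, []).append(h)

    out: list[RoleAssignment] = []
    for gene_id in sorted(by_gene):
        passing = [
            h for h in by_gene[gene_id]
            if h.evalue <= evalue_max and h.pfam_acc in catalog
        ]
        if not passing:
            out.append(RoleAssignment(gene_id=gene_id, role="none"))
            continue
        families: dict[str, list[DomainHit]] = {}
        for h in passing:
            families.setdefault(_family_of(catalog[h.pfam_acc]), []).append(h)
        ambiguous = len(families) > 1
        if ambiguous:
            # family of the best hit wins; tie -> lexicographic accession
            best = min(passing, key=lambda h: (-h.bitscore, h.pfam_acc))
            family = _family_of(catalog[best.pfam_acc])
        else:
            family = next(iter(families))
        fam_hits = tuple(sorted(
            families[family], key=lambda h: (-h.bitscore, h.pfam_acc, h.env_start)
        ))
        base_roles = {catalog[h.pfam_acc] for h in fam_hits}
        role = _resolve_family(base_roles, require_plug)
        out.append(RoleAssignment(
            gene_id=gene_id, role=role, supporting_hits=fam_hits,
            ambiguous=ambiguous,
        ))
    return out


def is_full_transducer(
    profile: Optional[SecondaryStructureProfile],
    protein_length: Optional[int] = None,
) -> Optional[bool]:
    """Does this transducer have room for all three domains?

    True iff a TMH is predicted and the protein is long enough that domain II
    (starting at TMH end + 1) is non-empty before the 100-residue C-terminal
    domain III.  Returns None (indeterminate) when no profile is available.
    """
    if profile is None:
        return None
    length = protein_length if protein_length is not None else len(profile)
    if profile.tmh_span is None:
        return False
    tmh_end = profile.tmh_span[1]
    return tmh_end + 1 <= length - 100
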