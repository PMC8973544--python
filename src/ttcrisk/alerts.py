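"""TTC-applicability screening of drug molecules.

The threshold-of-toxicological-concern approach cannot be applied to
every molecule: high-potency carcinogen classes (N-nitroso, azoxy and
aflatoxin-like compounds), highly bioaccumulative polyhalogenated
scaffolds, metal-containing drugs and proteins/biologics fall outside
the databases the TTC was derived from.  This module screens drug
records against a data-driven alert catalogue (``data/alerts.yaml``)
plus metal- and biologic-exclusion rules and reports, per molecule,
whether a TTC-based risk assessment is applicable and why not.

IARC carcinogenicity group is carried as pass-through metadata only; it
does not affect applicability.
"""

from __future__ import annotations

import csv
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml
from rdkit import Chem
from rdkit.Chem import Descriptors

__all__ = [
    "ORGANIC_ELEMENTS",
    "BIOLOGIC_MW_THRESHOLD",
    "DrugRecord",
    "AlertDefinition",
    "ScreenResult",
    "load_catalogue",
    "detect_metals",
    "match_alerts",
    "assess_ttc_applicability",
    "screen_panel",
    "read_drug_file",
    "load_reference_panel",
]

#: Elements considered "organic" for metal detection; anything outside
#: this set (As, Pt, Na, ...) flags the molecule as metal-containing.
ORGANIC_ELEMENTS = frozenset(
    {"H", "B", "C", "N", "O", "F", "Si", "P", "S", "Cl", "Br", "I"}
)

#: Molecules above this molecular weight (Da) without an explicit
#: is_biologic flag are treated as biologic-like, with a warning.
BIOLOGIC_MW_THRESHOLD = 2000.0

_HALOGEN_QUERY = Chem.MolFromSmarts("[F,Cl,Br,I]")

_IARC_GROUPS = {"1", "2A", "2B", "3", "unclassified"}


class CatalogueError(ValueError):
    """Raised when an alert catalogue fails to load or compile."""


@dataclass(frozen=True)
class DrugRecord:
    """A named drug: a SMILES structure and/or a biologic flag.

    At least one of ``smiles`` / ``is_biologic`` must be present —
    monoclonal antibodies have no meaningful SMILES, small molecules
    need one.
    """

    name: str
    smiles: str | None = None
    is_biologic: bool | None = None
    iarc_group: str = "unclassified"

    def __post_init__(self) -> None:
        if self.smiles is None and self.is_biologic is None:
            raise ValueError(
                f"{self.name}: need a SMILES structure or an is_biologic flag"
            )
        if self.iarc_group not in _IARC_GROUPS:
            raise ValueError(f"{self.name}: unknown IARC group {self.iarc_group!r}")


class AlertDefinition:
    """A named structural alert: one or more SMARTS, optional halogen gate.

    Patterns are compiled at construction; a bad SMARTS is a
    configuration error raised at load time, never at match time.
    """

    def __init__(
        self,
        alert_id: str,
        smarts: list[str],
        description: str = "",
        min_halogens: int | None = None,
    ) -> None:
        self.alert_id = alert_id
        self.description = description
        self.smarts = list(smarts)
        self.min_halogens = min_halogens
        self.queries = []
        for pattern in self.smarts:
            query = Chem.MolFromSmarts(pattern)
            if query is None:
                raise CatalogueError(
                    f"alert {alert_id!r}: SMARTS does not compile: {pattern!r}"
                )
            self.queries.append(query)

    def matches(self, mol: Chem.Mol) -> list[tuple[int, ...]]:
        """All substructure matches (atom index tuples); empty if gated out."""
        if self.min_halogens is not None:
            n_hal = len(mol.GetSubstructMatches(_HALOGEN_QUERY))
            if n_hal < self.min_halogens:
                return []
        hits: list[tuple[int, ...]] = []
        for query in self.queries:
            hits.extend(mol.GetSubstructMatches(query))
        return hits

    def __repr__(self) -> str:  # pragma: no cover
        return f"AlertDefinition({self.alert_id!r}, {len(self.smarts)} patterns)"


@dataclass(frozen=True)
class ScreenResult:
    """Per-molecule screening verdict.

    ``ttc_applicable`` is true exactly when ``exclusion_reasons`` is
    empty.  ``matched_atoms`` maps each triggered alert id to the set of
    atom indices involved in its matches.
    """

    name: str
    ttc_applicable: bool
    exclusion_reasons: tuple[str, ...]
    matched_atoms: dict = field(default_factory=dict)
    metal_elements: tuple[str, ...] = ()
    iarc_group: str = "unclassified"


def _default_catalogue_path():
    return resources.files("ttcrisk.data") / "alerts.yaml"


def load_catalogue(path: str | Path | None = None) -> list[AlertDefinition]:
    """Load and compile an alert catalogue from YAML.

    Without a path, the packaged cohort-of-concern catalogue is used.
    """
    source = Path(path) if path is not None else _default_catalogue_path()
    raw = yaml.safe_load(source.read_text())
    if not isinstance(raw, dict) or "alerts" not in raw:
        raise CatalogueError("catalogue YAML must contain a top-level 'alerts' list")
    catalogue = []
    seen = set()
    for entry in raw["alerts"]:
        definition = AlertDefinition(
            alert_id=entry["alert_id"],
            smarts=entry["smarts"],
            description=entry.get("description", ""),
            min_halogens=entry.get("min_halogens"),
        )
        if definition.alert_id in seen:
            raise CatalogueError(f"duplicate alert_id {definition.alert_id!r}")
        seen.add(definition.alert_id)
        catalogue.append(definition)
    return catalogue


def detect_metals(mol: Chem.Mol) -> dict:
    """Flag atoms outside the organic element set.

    Returns ``{"has_metal": bool, "elements": set of offending symbols}``.
    """
    offenders = {
        atom.GetSymbol()
        for atom in mol.GetAtoms()
        if atom.GetSymbol() not in ORGANIC_ELEMENTS
    }
    return {"has_metal": bool(offenders), "elements": offenders}


def match_alerts(
    mol: Chem.Mol, catalogue: list[AlertDefinition]
) -> list[str]:
    """Triggered alert ids, in catalogue order (deterministic)."""
    return [alert.alert_id for alert in catalogue if alert.matches(mol)]


def assess_ttc_applicability(
    record: DrugRecord,
    catalogue: list[AlertDefinition] | None = None,
    deny_list: tuple[str, ...] = (),
) -> ScreenResult:
    """Screen one drug record for TTC applicability.

    Exclusion reasons, in order of evaluation: ``protein`` (explicit
    biologic flag, or molecular weight above the biologic-like
    threshold), ``unparseable``, ``metal``, then any triggered
    structural alerts.  ``deny_list`` is an optional name-based cohort
    of hard-excluded drugs (case-insensitive), empty by default.
    """
    if catalogue is None:
        catalogue = load_catalogue()
    reasons: list[str] = []
    matched: dict = {}
    metal_elements: tuple[str, ...] = ()

    if record.name.lower() in {n.lower() for n in deny_list}:
        reasons.append("cohort_of_concern")

    if record.is_biologic:
        reasons.append("protein")
    elif record.smiles is None:
        # is_biologic explicitly False and no structure
        reasons.append("unparseable")
    else:
        mol = Chem.MolFromSmiles(record.smiles)
        if mol is None:
            reasons.append("unparseable")
        else:
            if (
                record.is_biologic is None
                and Descriptors.MolWt(mol) > BIOLOGIC_MW_THRESHOLD
            ):
                warnings.warn(
                    f"{record.name}: molecular weight exceeds "
                    f"{BIOLOGIC_MW_THRESHOLD:g} Da; treating as biologic-like",
                    stacklevel=2,
                )
                reasons.append("protein")
            metals = detect_metals(mol)
            if metals["has_metal"]:
                reasons.append("metal")
                metal_elements = tuple(sorted(metals["elements"]))
            for alert in catalogue:
                hits = alert.matches(mol)
                if hits:
                    reasons.append(alert.alert_id)
                    matched[alert.alert_id] = sorted(
                        {idx for hit in hits for idx in hit}
                    )

    return ScreenResult(
        name=record.name,
        ttc_applicable=not reasons,
        exclusion_reasons=tuple(reasons),
        matched_atoms=matched,
        metal_elements=metal_elements,
        iarc_group=record.iarc_group,
    )


def screen_panel(
    records: list[DrugRecord],
    catalogue: list[AlertDefinition] | None = None,
    deny_list: tuple[str, ...] = (),
) -> dict:
    """Screen a panel of drugs; returns counts plus per-record results.

    A record with several exclusion reasons is counted once under each
    reason.
    """
    if not records:
        raise ValueError("records must be non-empty")
    if catalogue is None:
        catalogue = load_catalogue()
    results = [
        assess_ttc_applicability(r, catalogue, deny_list) for r in records
    ]
    counts: dict[str, int] = {}
    for res in results:
        for reason in res.exclusion_reasons:
            counts[reason] = counts.get(reason, 0) + 1
    return {
        "n_total": len(results),
        "n_applicable": sum(r.ttc_applicable for r in results),
        "exclusion_counts": counts,
        "results": results,
    }


def _parse_bool(token: str) -> bool | None:
    token = token.strip().lower()
    if token in ("", "na", "none"):
        return None
    if token in ("true", "1", "yes", "y"):
        return True
    if token in ("false", "0", "no", "n"):
        return False
    raise ValueError(f"cannot parse boolean: {token!r}")


def read_drug_file(path: str | Path) -> list[DrugRecord]:
    """Read drug records from a ``.smi`` or CSV file.

    ``.smi``: whitespace-separated ``SMILES name`` per line (name may
    contain spaces).  CSV: columns ``name, smiles`` plus optional
    ``is_biologic`` and ``iarc_group``.
    """
    path = Path(path)
    if path.suffix.lower() == ".smi":
        records = []
        for line in path.read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            smiles, _, name = line.partition(" ")
            records.append(
                DrugRecord(name=name.strip() or smiles, smiles=smiles)
            )
        return records
    with open(path, newline="") as fh:
        rows = list(csv.DictReader(fh))
    records = []
    for row in rows:
        iarc = (row.get("iarc_group") or "").strip() or "unclassified"
        records.append(
            DrugRecord(
                name=row["name"].strip(),
                smiles=(row.get("smiles") or "").strip() or None,
                is_biologic=_parse_bool(row.get("is_biologic") or ""),
                iarc_group=iarc,
            )
        )
    return records


def load_reference_panel() -> list[DrugRecord]:
    """The packaged screening panel: common antineoplastic drugs plus
    reference carcinogens covering each alert class."""
    with resources.as_file(
        resources.files("ttcrisk.data") / "drug_panel.csv"
    ) as p:
        return read_drug_file(p)
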