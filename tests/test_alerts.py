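"""Structural screening: alert matching, metal/biologic exclusion, panel."""

import warnings

import pytest
from rdkit import Chem

from ttcrisk import (
    DrugRecord,
    assess_ttc_applicability,
    detect_metals,
    load_catalogue,
    match_alerts,
    screen_panel,
)
from ttcrisk.alerts import BIOLOGIC_MW_THRESHOLD, CatalogueError, read_drug_file


def mol(smiles):
    m = Chem.MolFromSmiles(smiles)
    assert m is not None, smiles
    return m


def by_name(panel, name):
    return next(r for r in panel if r.name == name)


# ---------------------------------------------------------------- metals


@pytest.mark.parametrize(
    "name,expect_metal,elements",
    [
        ("carboplatin", True, {"Pt"}),
        ("arsenic trioxide", True, {"As"}),
        ("cyclophosphamide", False, set()),
    ],
)
def test_metal_detection_on_panel(panel, name, expect_metal, elements):
    record = by_name(panel, name)
    out = detect_metals(mol(record.smiles))
    assert out["has_metal"] is expect_metal
    assert out["elements"] == elements


def test_ethanol_is_pure_organic():
    assert detect_metals(mol("CCO")) == {"has_metal": False, "elements": set()}


# ---------------------------------------------------------------- alerts


@pytest.mark.parametrize(
    "name,expected",
    [
        ("carmustine", ["n_nitroso"]),
        ("lomustine", ["n_nitroso"]),
        ("streptozocin", ["n_nitroso"]),
        ("cyclophosphamide", []),
        ("azoxymethane", ["azoxy"]),
        ("aflatoxin B1", ["aflatoxin_like"]),
        ("2,3,7,8-TCDD", ["polyhalogenated_scaffold"]),
        ("PCB 77", ["polyhalogenated_scaffold"]),
        ("5-fluorouracil", []),
        ("tamoxifen", []),  # biphenyl-free triphenylethylene, no halogens
        ("dacarbazine", []),  # triazene, not N-nitroso
        ("hydroxyurea", []),  # N-O single bond, not N-N=O
    ],
)
def test_alert_matching_on_panel(panel, catalogue, name, expected):
    record = by_name(panel, name)
    assert match_alerts(mol(record.smiles), catalogue) == expected


def test_halogen_gate_on_scaffolds(catalogue):
    # biphenyl/dioxin cores without >= 4 halogens do not fire
    assert match_alerts(mol("c1ccc(-c2ccccc2)cc1"), catalogue) == []
    assert match_alerts(mol("Clc1ccc(-c2ccccc2)cc1Cl"), catalogue) == []
    assert match_alerts(mol("c1ccc2Oc3ccccc3Oc2c1"), catalogue) == []


def naive_n_nitroso(m):
    """Independent oracle: atom-neighbourhood walk for N-N=O."""
    for atom in m.GetAtoms():
        if atom.GetSymbol() != "N" or atom.GetTotalDegree() != 3:
            continue
        for nbr in atom.GetNeighbors():
            if nbr.GetSymbol() != "N":
                continue
            for bond in nbr.GetBonds():
                other = bond.GetOtherAtom(nbr)
                if (
                    other.GetSymbol() == "O"
                    and bond.GetBondType() == Chem.BondType.DOUBLE
                ):
                    return True
    return False


def test_n_nitroso_matches_naive_atom_walk_on_full_panel(panel, catalogue):
    """SMARTS verdicts must agree with the independent walk on every fixture."""
    checked = 0
    for record in panel:
        if record.smiles is None:
            continue
        m = mol(record.smiles)
        assert ("n_nitroso" in match_alerts(m, catalogue)) == naive_n_nitroso(m), (
            record.name
        )
        checked += 1
    assert checked >= 25


def test_nitrogen_free_molecules_never_trigger_nitroso_or_azoxy(panel, catalogue):
    for record in panel:
        if record.smiles is None:
            continue
        m = mol(record.smiles)
        hits = set(match_alerts(m, catalogue))
        if not any(a.GetSymbol() == "N" for a in m.GetAtoms()):
            assert not hits & {"n_nitroso", "azoxy"}
        if not any(a.GetSymbol() in ("F", "Cl", "Br", "I") for a in m.GetAtoms()):
            assert "polyhalogenated_scaffold" not in hits


# ---------------------------------------------------------- applicability


def test_biologic_flag_excludes_as_protein():
    result = assess_ttc_applicability(DrugRecord("rituximab", is_biologic=True))
    assert not result.ttc_applicable
    assert result.exclusion_reasons == ("protein",)


def test_nitrosourea_not_applicable(panel, catalogue):
    result = assess_ttc_applicability(by_name(panel, "lomustine"), catalogue)
    assert not result.ttc_applicable
    assert result.exclusion_reasons == ("n_nitroso",)
    assert result.matched_atoms["n_nitroso"]  # atom indices reported


def test_clean_small_molecule_is_applicable(panel, catalogue):
    result = assess_ttc_applicability(by_name(panel, "5-fluorouracil"), catalogue)
    assert result.ttc_applicable
    assert result.exclusion_reasons == ()


def test_unparseable_smiles_flagged():
    result = assess_ttc_applicability(DrugRecord("bad", smiles="C1CC"))
    assert result.exclusion_reasons == ("unparseable",)


def test_record_requires_structure_or_flag():
    with pytest.raises(ValueError):
        DrugRecord("mystery")


def test_heavy_molecule_without_flag_is_biologic_like(catalogue):
    heavy = "C" * 150  # ~2.1 kDa alkane
    with pytest.warns(UserWarning, match="biologic-like"):
        result = assess_ttc_applicability(DrugRecord("megamer", smiles=heavy), catalogue)
    assert "protein" in result.exclusion_reasons
    assert Chem.Descriptors.MolWt(mol(heavy)) > BIOLOGIC_MW_THRESHOLD


def test_deny_list_hard_excludes_by_name(panel, catalogue):
    result = assess_ttc_applicability(
        by_name(panel, "melphalan"), catalogue, deny_list=("Melphalan",)
    )
    assert not result.ttc_applicable
    assert "cohort_of_concern" in result.exclusion_reasons


def test_iarc_group_is_metadata_only(panel, catalogue):
    # IARC group 1 alone never excludes
    result = assess_ttc_applicability(by_name(panel, "cyclophosphamide"), catalogue)
    assert result.iarc_group == "1"
    assert result.ttc_applicable


# ----------------------------------------------------------------- panel


def test_three_nitrosoureas_counted(panel, catalogue):
    trio = [by_name(panel, n) for n in ("carmustine", "lomustine", "streptozocin")]
    out = screen_panel(trio, catalogue)
    assert out["exclusion_counts"]["n_nitroso"] == 3
    assert out["n_applicable"] == 0


def test_panel_counts_consistent_with_individual_calls(panel, catalogue):
    out = screen_panel(panel, catalogue)
    singles = [assess_ttc_applicability(r, catalogue) for r in panel]
    assert out["n_total"] == len(panel)
    assert out["n_applicable"] == sum(r.ttc_applicable for r in singles)
    for reason, count in out["exclusion_counts"].items():
        assert count == sum(reason in r.exclusion_reasons for r in singles)


def test_screening_is_pure_and_context_free(panel, catalogue):
    single = assess_ttc_applicability(panel[0], catalogue)
    again = assess_ttc_applicability(panel[0], catalogue)
    assert single == again
    # verdict unchanged when screened amid unrelated records
    in_panel = screen_panel(panel, catalogue)["results"][0]
    assert in_panel == single


def test_empty_panel_rejected(catalogue):
    with pytest.raises(ValueError):
        screen_panel([], catalogue)


# ------------------------------------------------------------- I/O, data


def test_smi_and_csv_readers(tmp_path):
    smi = tmp_path / "drugs.smi"
    smi.write_text("CCO ethanol\nc1ccccc1 benzene\n# comment\n")
    records = read_drug_file(smi)
    assert [r.name for r in records] == ["ethanol", "benzene"]

    csv_path = tmp_path / "drugs.csv"
    csv_path.write_text(
        "name,smiles,is_biologic,iarc_group\n"
        "ethanol,CCO,,\n"
        "mab,,true,\n"
    )
    records = read_drug_file(csv_path)
    assert records[0].iarc_group == "unclassified"
    assert records[1].is_biologic is True


def test_bad_catalogue_fails_at_load(tmp_path):
    bad = tmp_path / "bad.yaml"
    bad.write_text("alerts:\n  - alert_id: broken\n    smarts: ['[N+++']\n")
    with pytest.raises(CatalogueError):
        load_catalogue(bad)
    dup = tmp_path / "dup.yaml"
    dup.write_text(
        "alerts:\n"
        "  - alert_id: a\n    smarts: ['[N]']\n"
        "  - alert_id: a\n    smarts: ['[O]']\n"
    )
    with pytest.raises(CatalogueError):
        load_catalogue(dup)


def test_reference_panel_all_structures_parse(panel):
    with warnings.catch_warnings():
        warnings.simplefilter("error")  # no MW-heuristic warnings expected
        out = screen_panel(panel)
    for result in out["results"]:
        assert "unparseable" not in result.exclusion_reasons
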