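"""Data module: tabular I/O, benchmark reader, splits, synthetic law."""

import json

import numpy as np
import pytest
from rdkit import Chem

from dtagnn.data import (
    AffinityRecord,
    HYDROPHOBIC_RESIDUES,
    AROMATIC_RESIDUES,
    SyntheticSpec,
    generate_synthetic_dataset,
    neg_log10_nanomolar,
    read_benchmark_dir,
    read_pairs_table,
    smiles_template_library,
    train_test_split,
    write_pairs_table,
)
from dtagnn.errors import InputError, SchemaError
from dtagnn.molgraph import smiles_to_graph


def make_records(n=3):
    return [
        AffinityRecord(f"d{i}", "CCO", f"p{i}", "ACDEF", float(i)) for i in range(n)
    ]


# -- pairs tables -----------------------------------------------------------


def test_pairs_round_trip(tmp_path):
    path = tmp_path / "pairs.csv"
    records = make_records()
    write_pairs_table(records, path)
    loaded = read_pairs_table(path)
    assert [(r.drug_id, r.smiles, r.protein_id, r.sequence, r.affinity)
            for r in loaded] == [
        (r.drug_id, r.smiles, r.protein_id, r.sequence, r.affinity) for r in records
    ]


def test_missing_column_is_schema_error(tmp_path):
    path = tmp_path / "bad.csv"
    path.write_text("drug_id,smiles,affinity\nd1,CCO,1.0\n")
    with pytest.raises(SchemaError, match="missing column"):
        read_pairs_table(path)


def test_bad_smiles_row_strict_vs_permissive(tmp_path):
    path = tmp_path / "pairs.csv"
    path.write_text(
        "drug_id,smiles,protein_id,sequence,affinity\n"
        "d1,CCO,p1,ACD,1.0\n"
        "d2,(((,p2,ACD,2.0\n"
    )
    with pytest.raises(SchemaError, match="row 2"):
        read_pairs_table(path, strict=True)
    loaded = read_pairs_table(path, strict=False)
    assert [r.drug_id for r in loaded] == ["d1"]


# -- benchmark directory ----------------------------------------------------


def write_benchmark(tmp_path, matrix_rows):
    (tmp_path / "drugs.json").write_text(json.dumps({"d1": "CCO", "d2": "c1ccccc1"}))
    (tmp_path / "proteins.json").write_text(
        json.dumps({"p1": "ACD", "p2": "MKV", "p3": "WYW"})
    )
    (tmp_path / "affinities.tsv").write_text(
        "drug\tp1\tp2\tp3\n" + "\n".join(matrix_rows) + "\n"
    )


def test_full_matrix_yields_one_record_per_cell(tmp_path):
    write_benchmark(tmp_path, ["d1\t1.0\t2.0\t3.0", "d2\t4.0\t5.0\t6.0"])
    records = read_benchmark_dir(tmp_path)
    assert len(records) == 6
    assert {(r.drug_id, r.protein_id) for r in records} == {
        (d, p) for d in ("d1", "d2") for p in ("p1", "p2", "p3")
    }


def test_missing_cell_is_dropped(tmp_path):
    write_benchmark(tmp_path, ["d1\t1.0\t\t3.0", "d2\t4.0\t5.0\t6.0"])
    assert len(read_benchmark_dir(tmp_path)) == 5


def test_nanomolar_transform_maps_10000_to_5(tmp_path):
    assert neg_log10_nanomolar(10000) == pytest.approx(5.0)
    write_benchmark(tmp_path, ["d1\t10000\t10000\t10000", "d2\t1\t1\t1"])
    records = read_benchmark_dir(tmp_path, affinity_transform="neg_log10_nanomolar")
    by_drug = {r.drug_id: r.affinity for r in records}
    assert by_drug["d1"] == pytest.approx(5.0)
    assert by_drug["d2"] == pytest.approx(9.0)


def test_unknown_matrix_id_is_consistency_error(tmp_path):
    write_benchmark(tmp_path, ["d1\t1\t2\t3", "d9\t4\t5\t6"])
    with pytest.raises(SchemaError, match="d9"):
        read_benchmark_dir(tmp_path)


# -- splits -----------------------------------------------------------------


def test_split_sizes_and_reproducibility():
    records = make_records(100)
    tr1, te1 = train_test_split(records, 0.2, seed=9)
    tr2, te2 = train_test_split(records, 0.2, seed=9)
    assert len(tr1) == 80 and len(te1) == 20
    assert [r.drug_id for r in tr1] == [r.drug_id for r in tr2]
    assert [r.drug_id for r in te1] == [r.drug_id for r in te2]


def test_split_is_disjoint_and_exhaustive():
    records = make_records(57)
    tr, te = train_test_split(records, 0.3, seed=1)
    ids = sorted(r.drug_id for r in tr + te)
    assert ids == sorted(r.drug_id for r in records)
    assert not ({r.drug_id for r in tr} & {r.drug_id for r in te})


def test_different_seeds_give_different_memberships():
    records = make_records(100)
    base = {r.drug_id for r in train_test_split(records, 0.2, seed=0)[1]}
    assert any(
        {r.drug_id for r in train_test_split(records, 0.2, seed=s)[1]} != base
        for s in range(1, 11)
    )


def test_bad_fraction_rejected():
    with pytest.raises(InputError):
        train_test_split(make_records(), 0.0, seed=0)


# -- synthetic generator ----------------------------------------------------


def test_library_is_valid_and_spans_sizes():
    library = smiles_template_library()
    assert len(library) >= 60
    sizes, arom = [], []
    for smi in library:
        mol = Chem.MolFromSmiles(smi)
        assert mol is not None, smi
        sizes.append(mol.GetNumAtoms())
        arom.append(sum(a.GetIsAromatic() for a in mol.GetAtoms()) / mol.GetNumAtoms())
    assert min(sizes) == 1 and max(sizes) >= 20
    assert min(arom) == 0.0 and max(arom) == 1.0


def test_same_seed_is_byte_identical():
    spec = SyntheticSpec(n_drugs=10, n_proteins=5, n_pairs=30, seed=4)
    a = generate_synthetic_dataset(spec)
    b = generate_synthetic_dataset(SyntheticSpec(n_drugs=10, n_proteins=5, n_pairs=30, seed=4))
    assert [(r.drug_id, r.smiles, r.sequence, r.affinity) for r in a] == [
        (r.drug_id, r.smiles, r.sequence, r.affinity) for r in b
    ]


def test_full_grid_enumerates_every_pair_once():
    spec = SyntheticSpec(n_drugs=6, n_proteins=4, n_pairs=24, seed=0)
    records = generate_synthetic_dataset(spec)
    assert len({(r.drug_id, r.protein_id) for r in records}) == 24


def test_oversized_grid_rejected():
    with pytest.raises(InputError):
        SyntheticSpec(n_drugs=2, n_proteins=2, n_pairs=5).validate()


def test_all_generated_smiles_featurize():
    records = generate_synthetic_dataset(SyntheticSpec(seed=2))
    for smi in {r.smiles for r in records}:
        assert smiles_to_graph(smi).num_nodes >= 1


def test_noiseless_law_recomputable_by_descriptor_oracle():
    """With noise_sd = 0 the affinity equals the descriptor law recomputed
    from scratch (z-scored heavy atoms, hydrophobic fraction, interaction)."""
    spec = SyntheticSpec(n_drugs=20, n_proteins=10, n_pairs=150, noise_sd=0.0, seed=8)
    records = generate_synthetic_dataset(spec)

    def z(v):
        v = np.asarray(v, dtype=float)
        return (v - v.mean()) / v.std()

    heavy, arom_atoms, hydro, arom_res = [], [], [], []
    for r in records:
        mol = Chem.MolFromSmiles(r.smiles)
        heavy.append(mol.GetNumAtoms())
        arom_atoms.append(sum(a.GetIsAromatic() for a in mol.GetAtoms()))
        hydro.append(sum(c in HYDROPHOBIC_RESIDUES for c in r.sequence) / len(r.sequence))
        arom_res.append(sum(c in AROMATIC_RESIDUES for c in r.sequence) / len(r.sequence))
    law = z(
        spec.alpha * z(heavy)
        + spec.beta * z(hydro)
        + spec.gamma * z(np.array(arom_atoms, dtype=float) * np.array(arom_res))
    )
    affinities = np.array([r.affinity for r in records])
    np.testing.assert_allclose(affinities, law, atol=1e-10)
    np.testing.assert_allclose(affinities, [r.affinity_true for r in records])
    assert np.std(affinities) == pytest.approx(1.0)


def test_law_depends_on_protein_branch():
    """With β = γ = 0 the affinity is a drug-only function; with the default
    coefficients the same drug spans different affinities across proteins."""
    drug_only = generate_synthetic_dataset(
        SyntheticSpec(n_drugs=5, n_proteins=10, n_pairs=50, noise_sd=0.0,
                      beta=0.0, gamma=0.0, seed=3)
    )
    by_drug = {}
    for r in drug_only:
        by_drug.setdefault(r.drug_id, set()).add(round(r.affinity_true, 9))
    assert all(len(v) == 1 for v in by_drug.values())

    full = generate_synthetic_dataset(
        SyntheticSpec(n_drugs=5, n_proteins=10, n_pairs=50, noise_sd=0.0, seed=3)
    )
    by_drug = {}
    for r in full:
        by_drug.setdefault(r.drug_id, set()).add(round(r.affinity_true, 9))
    assert any(len(v) > 1 for v in by_drug.values())
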