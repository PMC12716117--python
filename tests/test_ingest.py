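"""PSM table I/O, E-value ceiling, and target-decoy FDR filtering."""

import numpy as np
import pandas as pd
import pytest

from proformquant.core import PsmRecord
from proformquant.ingest import (compute_qvalues, evalue_ceiling, fdr_filter,
                                 frame_to_records, read_psm_table,
                                 records_to_frame, write_psm_table)


def _records():
    return [
        PsmRecord("ds1", 1, 10.0, 3000.5, "P01308", "INS", 25, 54,
                  [(15.9949, "31-31")], 1e-6, False, 2e6, "-45"),
        PsmRecord("ds1", 2, 20.0, 5000.25, "P01275", "GCG", 53, 81,
                  [], 1e-4, False, 1e5, "-55"),
        PsmRecord("ds1", 3, 30.0, 9000.125, "DECOY_X", "", 1, 1,
                  [], 0.5, True, np.nan, "-35"),
    ]


def test_round_trip(tmp_path):
    frame = records_to_frame(_records())
    path = tmp_path / "psms.tsv"
    write_psm_table(frame, path)
    table = read_psm_table(path)
    assert len(table) == 3
    back = table.records()
    for orig, new in zip(_records(), back):
        assert new.dataset_id == orig.dataset_id
        assert new.mass_da == pytest.approx(orig.mass_da)
        assert new.rt_min == pytest.approx(orig.rt_min)
        assert new.is_decoy == orig.is_decoy
        assert new.mod_shifts_da == [
            (round(d, 4), loc) for d, loc in orig.mod_shifts_da]


def test_malformed_row_dropped_and_counted(tmp_path):
    frame = records_to_frame(_records()).astype({"mass_da": object})
    frame.loc[1, "mass_da"] = "not-a-mass"
    path = tmp_path / "psms.tsv"
    frame.to_csv(path, sep="\t", index=False)
    table = read_psm_table(path)
    assert len(table) == 2
    assert table.n_dropped == 1


def test_missing_mandatory_column_named(tmp_path):
    frame = records_to_frame(_records()).drop(columns=["evalue"])
    path = tmp_path / "psms.tsv"
    frame.to_csv(path, sep="\t", index=False)
    with pytest.raises(ValueError, match="evalue"):
        read_psm_table(path)


def test_alternate_dialect_equals_canonical(tmp_path):
    """The same data under foreign headers + column_map reads identically."""
    frame = records_to_frame(_records())
    canonical = tmp_path / "canonical.tsv"
    write_psm_table(frame, canonical)
    column_map = {"scan": "Scan(s)", "rt_min": "Retention time",
                  "mass_da": "Precursor mass", "evalue": "E-value"}
    foreign = frame.rename(columns=column_map)
    foreign_path = tmp_path / "foreign.tsv"
    foreign.to_csv(foreign_path, sep="\t", index=False)
    t1 = read_psm_table(canonical, dataset_id="ds1")
    t2 = read_psm_table(foreign_path, column_map=column_map,
                        dataset_id="ds1")
    pd.testing.assert_frame_equal(t1.frame, t2.frame)


def test_decoy_fallback_from_accession_prefix(tmp_path):
    frame = records_to_frame(_records())
    frame["is_decoy"] = ""
    path = tmp_path / "psms.tsv"
    frame.to_csv(path, sep="\t", index=False)
    table = read_psm_table(path)
    assert list(table.frame["is_decoy"]) == [False, False, True]


# ---------------------------------------------------------------------------
# E-value ceiling


def test_evalue_ceiling_boundary_inclusive():
    frame = pd.DataFrame({"evalue": [0.01, 0.05, 0.06]})
    assert len(evalue_ceiling(frame, 0.05)) == 2
    assert len(evalue_ceiling(frame.iloc[0:0], 0.05)) == 0


def test_evalue_ceiling_matches_direct_count():
    rng = np.random.default_rng(3)
    ev = rng.uniform(0, 0.1, 100)
    frame = pd.DataFrame({"evalue": ev})
    assert len(evalue_ceiling(frame, 0.05)) == int((ev <= 0.05).sum())


# ---------------------------------------------------------------------------
# FDR filtering


def _frame(labels, evalues=None):
    n = len(labels)
    evalues = evalues if evalues is not None else np.arange(1, n + 1) * 1e-3
    return pd.DataFrame({
        "dataset_id": "ds1", "evalue": evalues,
        "is_decoy": [c == "D" for c in labels]})


def qvalue_oracle(evalues, is_decoy):
    """Hand-rolled running-ratio oracle (independent of the implementation)."""
    order = sorted(range(len(evalues)), key=lambda i: (evalues[i], is_decoy[i]))
    running = []
    d = t = 0
    for i in order:
        d += is_decoy[i]
        t += not is_decoy[i]
        running.append(d / max(1, t))
    q_sorted = running[:]
    for j in range(len(q_sorted) - 2, -1, -1):
        q_sorted[j] = min(q_sorted[j], q_sorted[j + 1])
    q = [0.0] * len(evalues)
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return q


def test_fdr_hand_computed_examples():
    kept, _ = fdr_filter(_frame(list("TTTDT")), target_fdr=0.25)
    assert len(kept) == 4
    kept, _ = fdr_filter(_frame(list("TD")), target_fdr=0.01)
    assert len(kept) == 1
    kept, info = fdr_filter(_frame(list("TTTT")), target_fdr=0.01)
    assert len(kept) == 4  # no decoys: FDR estimate 0 everywhere
    assert info["threshold"] == pytest.approx(4e-3)


def test_fdr_qvalues_match_oracle_on_20_record_fixture():
    rng = np.random.default_rng(11)
    ev = rng.uniform(0, 1, 20)
    decoy = rng.random(20) < 0.4
    decoy[np.argmin(ev)] = False  # keep at least one confident target
    q = compute_qvalues(ev, decoy)
    assert np.allclose(q, qvalue_oracle(list(ev), list(decoy)))


def test_fdr_ties_keep_targets_before_decoys():
    frame = _frame(list("TD"), evalues=[0.01, 0.01])
    q = compute_qvalues(frame["evalue"], frame["is_decoy"])
    assert q[0] == 0.0  # target ranked first at the tied score


def test_fdr_monotone_in_target():
    rng = np.random.default_rng(5)
    frame = _frame(rng.choice(["T", "D"], 200, p=[0.8, 0.2]),
                   evalues=rng.uniform(0, 1, 200))
    sizes = [len(fdr_filter(frame, f)[0])
             for f in (0.001, 0.01, 0.05, 0.2, 0.5, 1.0)]
    assert sizes == sorted(sizes)


def test_fdr_zero_targets_warns_empty():
    kept, info = fdr_filter(_frame(list("DD")), target_fdr=0.1)
    assert len(kept) == 0 and info["n_kept"] == 0


def test_fdr_per_dataset_partitions():
    frame = pd.concat([_frame(list("TTTDT")).assign(dataset_id="a"),
                       _frame(list("TTTT")).assign(dataset_id="b")],
                      ignore_index=True)
    kept, info = fdr_filter(frame, 0.25, per_dataset=True)
    assert set(kept["dataset_id"]) == {"a", "b"}
    assert set(info["per_dataset"]) == {"a", "b"}


def test_realized_fdp_controlled_on_simulated_mixture():
    """With entrapment false targets matching the decoy score distribution,
    the realized false-discovery proportion at q <= 0.01 stays near target."""
    rng = np.random.default_rng(42)
    fdps = []
    for _ in range(100):
        n_true, n_false, n_decoy = 400, 100, 100
        ev = np.concatenate([
            10.0 ** -(1.0 + rng.gamma(2.0, 1.5, n_true)),  # true targets
            rng.uniform(0, 1, n_false),                    # false targets
            rng.uniform(0, 1, n_decoy)])                   # decoys
        is_decoy = np.r_[np.zeros(n_true + n_false, bool), np.ones(n_decoy, bool)]
        is_false = np.r_[np.zeros(n_true, bool), np.ones(n_false, bool),
                         np.zeros(n_decoy, bool)]
        frame = pd.DataFrame({"dataset_id": "ds", "evalue": ev,
                              "is_decoy": is_decoy, "is_false": is_false})
        kept, _ = fdr_filter(frame, target_fdr=0.01)
        if len(kept):
            fdps.append(kept["is_false"].mean())
    assert np.mean(fdps) <= 0.03
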