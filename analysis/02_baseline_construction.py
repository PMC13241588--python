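"""QC, sibling pruning, and aggregation of baseline collections.

Reproduces the baseline-construction chain: call-rate and locus filters,
pairwise relatedness screening (keep two per full-sib family), pairwise
and global Weir--Cockerham FST, leave-one-out self-assignment, iterative
aggregation of confusable same-stream collection pairs, and exclusion of
tiny leftover collections.  Writes the reporting-unit table consumed by
03_mixture_assignment.py.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))
sys.path.insert(0, str(Path(__file__).resolve().parent))

import numpy as np
import pandas as pd

from common import RESULTS, demo_config
from rivergsi import baseline as bl
from rivergsi import relatedness
from rivergsi.pipeline import qc_stage
from rivergsi.riverscape import simulate_riverscape


def build_baseline(cfg):
    rs = simulate_riverscape(cfg.simulation)
    G_all, _ = qc_stage(rs.baseline.concat(rs.mixture), cfg.thresholds)
    is_base = (G_all.meta["role"] == "baseline").to_numpy()
    G_base = G_all.take_individuals(np.flatnonzero(is_base))
    G_base, pairs, fams = relatedness.sibling_filter(
        G_base, cfg.thresholds.sib_relatedness)
    stream_of = rs.stream_of_collection()
    grouping, merge_log = bl.aggregate_collections(
        G_base, stream_of, cfg.thresholds.self_assignment,
        cfg.thresholds.fst_merge)
    units = bl.build_units(G_base, grouping, stream_of)
    units, excluded = bl.exclude_small_collections(
        units, cfg.thresholds.small_collection)
    keep = {c for u in units for c in u.collection_ids}
    G_base = G_base.take_individuals(np.flatnonzero(
        G_base.meta["collection_id"].isin(keep).to_numpy()))
    return rs, G_all, G_base, units, merge_log, excluded, fams


def main():
    cfg = demo_config()
    rs, G_all, G_base, units, merge_log, excluded, fams = build_baseline(cfg)
    unit_of = {c: u.unit_id for u in units for c in u.collection_ids}
    _, conf = bl.self_assignment_loo(G_base, unit_of)
    fst = bl.weir_cockerham_fst(G_base, unit_of)

    out = RESULTS / "baseline"
    out.mkdir(parents=True, exist_ok=True)
    conf.probabilities.to_csv(out / "confusion.csv")
    pd.DataFrame(fst.matrix, index=fst.ids, columns=fst.ids).to_csv(out / "fst.csv")
    merge_log.to_csv(out / "merge_log.csv", index=False)
    excluded.to_csv(out / "excluded_collections.csv", index=False)
    pd.DataFrame([{"unit": u.unit_id, "collections": "+".join(u.collection_ids),
                   "n": u.n_individuals, "stream": u.stream_id}
                  for u in units]).to_csv(out / "units.csv", index=False)

    w = {u.unit_id: u.n_individuals for u in units}
    rates = conf.self_rates()
    iu = np.triu_indices(len(fst.ids), 1)
    print(f"{len(units)} reporting units from "
          f"{G_all.meta.loc[G_all.meta.role == 'baseline', 'collection_id'].nunique()} "
          f"collections ({len(merge_log)} merges, {len(excluded)} excluded)")
    print(f"sibling filter pruned "
          f"{int((~fams['retained']).sum()) if len(fams) else 0} fish")
    print(f"global FST = {fst.global_theta:.3f}; "
          f"{100 * (fst.matrix[iu] > 0.01).mean():.1f}% of pairwise values > 0.01")
    print(f"self-assignment: range {rates.min():.2f}-{rates.max():.2f}, "
          f"weighted mean {conf.weighted_mean_self_rate(w):.2f}")
    print(f"tables in {out}")


if __name__ == "__main__":
    main()
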