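"""End-to-end run: simulate a cohort directory, analyse it, read the report.

Equivalent to the CLI sequence
    pediconn simulate --out cohort --seed 42
    pediconn run-all cohort --out results --n-perm 500 --seed 42
but driven from Python.  Uses a reduced permutation count for speed.
"""

import tempfile
from pathlib import Path

from pediconn import (
    RunConfig,
    generate_cohort,
    preset_paper_like,
    run_full_analysis,
    write_cohort,
)

with tempfile.TemporaryDirectory() as tmp:
    cohort_dir = Path(tmp) / "cohort"
    out_dir = Path(tmp) / "results"

    cfg = preset_paper_like(seed=42)
    cohort, truth = generate_cohort(cfg)
    write_cohort(cohort, cohort_dir, ground_truth=truth, config=cfg)
    print(f"simulated {len(cohort)} subjects into {cohort_dir}")

    tables = run_full_analysis(
        RunConfig(
            cohort_dir=str(cohort_dir),
            output_dir=str(out_dir),
            nbs_n_perm=500,
            seed=42,
        )
    )

    gs = tables["global_stats"]
    print("\nglobal measures (group t, interaction p):")
    for _, r in gs.iterrows():
        print(f"  {r['measure']:>8}: t = {r['group_t']:+.3f}, "
              f"interaction p = {r['interaction_p']:.4f}")

    ns = tables["nodal_stats"]
    sig = ns[ns["group_significant"]]
    print(f"\nFDR-significant regions: {len(sig)}")
    print("hubs (TD):", ", ".join(tables["hubs_td"]["node"]))
    print("hubs (ASD):", ", ".join(tables["hubs_asd"]["node"]))

    nbs = tables["nbs_components"]
    if not nbs.empty:
        c0 = nbs[nbs["component"] == 0]
        print(f"\nlargest NBS component: {c0['size'].iloc[0]} edges, "
              f"corrected p = {c0['corrected_p'].iloc[0]:.4f}")
    cc = tables["clinical_correlations"]
    sig_cc = cc[cc["p"] < 0.05]
    print(f"significant clinical correlations: {len(sig_cc)} "
          f"of {len(cc)} tested (ASD only, age-adjusted)")
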