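"""Fit the signed cluster weights (per biologic event) and the scaling
factors coupling the networks to wall growth; save the full hybrid model.

The weight stage represents each measured event-rate course as a constrained
linear combination of the calibrated networks' trajectories (weights in
[-1, 1], absolute values summing to 1). The scaling stage then runs the
coupled model per GA candidate against the intimal-thickness course and
reports the final normalized fit error (PRMS).
"""

import json
import sys
from pathlib import Path

import numpy as np

import graftnet as gn
from graftnet import io
from graftnet.calibration import calibrate_scaling, calibrate_weights
from graftnet.core import ScalingFactors
from graftnet.hybrid import HybridParameters
from graftnet.network import simulate_network

SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 0
ROOT = Path(__file__).resolve().parent.parent / "results"
DATA = ROOT / "dataset"
OUT = ROOT / "calibration"


def main() -> None:
    grid = gn.TimeGrid()
    events = io.read_timecourse_table(DATA / "events.csv", "events", grid=grid)
    morph = io.read_timecourse_table(DATA / "morphology.csv", "morphology", grid=grid)

    cn, g0, curves = {}, {}, {}
    for net in gn.NETWORK_IDS:
        cn[net] = io.load_cn_parameters(OUT / f"cn_{net.lower()}.json")
        payload = json.loads((OUT / f"g0_{net.lower()}.json").read_text())
        g0[net] = np.asarray(payload["data"]["g0"], dtype=float)
        curves[net] = simulate_network(cn[net], g0[net], grid)

    wres = calibrate_weights(curves, events, gn.GAConfig(
        pop_multiplier=60, generations=60, n_restarts=2, n_runs=2, seed=SEED + 17))
    for net, wv in wres.params.items():
        print(f"{net} weights: {np.round(wv.w, 3)}")

    partial = HybridParameters(
        cn=cn, g0=g0, weights=wres.params,
        scaling=ScalingFactors(np.ones(5), np.ones(5), np.ones(5)),
        scenario=gn.VesselState(),
    )
    sres = calibrate_scaling(
        partial,
        morph["time_days"].to_numpy(dtype=float),
        morph["intimal_thickness_mm"].to_numpy(dtype=float),
        gn.GAConfig(pop_multiplier=40, generations=80, n_restarts=4,
                    restart_shrink=0.08, n_runs=2, seed=SEED + 23),
    )
    model = sres.extras["hybrid"]
    io.save_hybrid_parameters(model, OUT / "hybrid_parameters.json")
    print(f"scaling stage: thickness PRMS = {sres.extras['prms_percent']:.3f}% "
          f"(fit quality target: < 1%)")
    (OUT / "hybrid_summary.json").write_text(json.dumps({
        "weights_objective": wres.objective,
        "scaling_objective": sres.objective,
        "prms_percent": sres.extras["prms_percent"],
    }, indent=2))


if __name__ == "__main__":
    main()
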