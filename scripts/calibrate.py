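#!/usr/bin/env python
"""Coarse parameter scan behind the default patterning parameter set.

The kinetic scales are fixed up front (c_A = d_A = c_P = d_P = V_X =
d_X = 1, K_XA = 1, n_XA = 4, f_p = 1), which pins the uniform state at
A* = P* = 1, X* = 0.5 with the X activation at its most sensitive
point.  The scan then varies the three couplings that decide whether
and where patterns form:

  T    — active transport strength,
  k_p  — weight of polarized exocytosis,
  V_X  — X production ceiling,

and scores each combination on the two required behaviors:

  1. spontaneous patterning: peak-to-trough ratio > 2 with >= 1 peak on
     the null-prepattern disc and the noise-seeded ring;
  2. boundary restriction: >= 90% of peaks inside the KAN/REV boundary
     annulus when the prepattern is applied.

Usage:
    python scripts/calibrate.py [--cells 200] [--seed 0]

The default ModelParams in pinpattern.dynamics record the chosen point
(T = 20, k_p = 1, V_X = 1), which sits comfortably inside the passing
region rather than on its edge.
"""

from __future__ import annotations

import argparse
from dataclasses import replace

import numpy as np

import pinpattern as pp


def evaluate(params, disc, ring, field, mask, seed):
    out = {}
    traj = pp.simulate(disc, None, params, 300.0)
    A = traj.final.A
    peaks = pp.detect_peaks(traj.final, disc)
    out["disc_p2t"] = float(A.max() / A.min())
    out["disc_peaks"] = len(peaks)

    traj = pp.simulate(
        ring, None, params, 150.0, perturbation=pp.NoiseSpec(sd=0.05, seed=seed)
    )
    A = traj.final.A
    out["ring_p2t"] = float(A.max() / A.min())
    out["ring_peaks"] = len(pp.detect_peaks(traj.final, ring))

    traj = pp.simulate(disc, field, params, 300.0)
    peaks_on = pp.detect_peaks(traj.final, disc)
    out["on_peaks"] = len(peaks_on)
    out["score"] = (
        pp.boundary_restriction_score(peaks_on, mask) if len(peaks_on) else float("nan")
    )
    out["patterns"] = (
        out["disc_p2t"] > 2 and out["disc_peaks"] >= 1
        and out["ring_p2t"] > 2 and out["ring_peaks"] >= 1
    )
    out["restricted"] = len(peaks_on) >= 1 and out["score"] >= 0.9
    return out


def main():
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--cells", type=int, default=200)
    ap.add_argument("--seed", type=int, default=0)
    args = ap.parse_args()

    disc = pp.generate_disc_tissue(args.cells, 60.0, seed=args.seed, relaxation_steps=10)
    ring = pp.generate_ring_tissue(100)
    r = pp.radial_coordinate(disc)
    field = pp.prepattern_equilibrium(r, pp.PrepatternParams())
    mask = pp.boundary_mask(field, 0.5)

    base = pp.ModelParams()
    header = f"{'T':>6} {'k_p':>5} {'V_X':>5} | {'disc_p2t':>9} {'peaks':>5} {'ring_p2t':>9} {'score':>6} | verdict"
    print(header)
    print("-" * len(header))
    for T in (2.0, 5.0, 10.0, 20.0, 40.0):
        for k_p in (0.5, 0.8, 1.0):
            for V_X in (0.5, 1.0, 2.0):
                prm = replace(base, T=T, k_p=k_p, V_X=V_X)
                try:
                    res = evaluate(prm, disc, ring, field, mask, args.seed)
                except pp.IntegrationError:
                    print(f"{T:6.1f} {k_p:5.2f} {V_X:5.2f} | integration failure")
                    continue
                verdict = (
                    "PASS" if res["patterns"] and res["restricted"]
                    else "pattern-only" if res["patterns"]
                    else "-"
                )
                print(
                    f"{T:6.1f} {k_p:5.2f} {V_X:5.2f} | "
                    f"{res['disc_p2t']:9.2f} {res['disc_peaks']:5d} "
                    f"{res['ring_p2t']:9.2f} {res['score']:6.2f} | {verdict}"
                )


if __name__ == "__main__":
    main()
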