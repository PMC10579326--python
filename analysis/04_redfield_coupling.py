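#!/usr/bin/env python
"""Couple methane formation to primary production: the Redfield phosphate
demand of the surface median carbon-fixation rate (371 nmol C L-1 d-1) and
the share of it the measured methane (= phosphate liberation, 1:1) rates
could sustain.  Reads results/campaign/rates.tsv."""

from pathlib import Path

import pandas as pd

from mpnmethane.coupling import redfield_pi_demand, support_distribution

CFIX_SURFACE = 371.0  # nmol C L-1 d-1, surface median carbon fixation

out = Path("results/campaign")
rates = pd.read_csv(out / "rates.tsv", sep="\t")
surface = rates[(rates.treatment == "MPn")
                & (rates.depth_category == "surface")]["net_rate"]

demand = redfield_pi_demand(CFIX_SURFACE)
dist = support_distribution(surface, CFIX_SURFACE)
pd.DataFrame([dict(dist, pi_demand=demand, cfix_rate=CFIX_SURFACE)]) \
    .to_csv(out / "coupling.tsv", sep="\t", index=False)

print(f"Redfield Pi demand of {CFIX_SURFACE:.0f} nmol C L-1 d-1: "
      f"{demand:.1f} nmol P L-1 d-1")
print(f"phosphonate-derived Pi could support {dist['min']:.0f}-"
      f"{dist['max']:.1f}% (median {dist['median']:.0f}%) of it "
      f"(n = {dist['n']} surface incubations)")
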