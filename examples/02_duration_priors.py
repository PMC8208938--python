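"""Compare the imprecise and precise context-duration priors.

Both priors have mean dwell time ~5 segments, but the precise one
concentrates there, which turns the induced change probability rho(tau) from
a flat hazard (a plain HMM) into a profile peaked at multiples of five —
the basis of anticipatory meta-control.
"""

import numpy as np

from metabandit import effective_change_probability, make_duration_prior

for name, (theta, beta) in (("imprecise", (1.0, 0.2)),
                            ("precise", (20.0, 4.0))):
    prior = make_duration_prior(theta, beta, D=20)
    rho = effective_change_probability(prior, tau_max=15).rho
    print(f"{name} prior (theta={theta}, beta={beta}):")
    print(f"  dwell mean {prior.mean:.2f}, variance {prior.variance:.2f}")
    print("  rho(tau), tau=1..15:", np.round(rho, 3))
    shape = ("flat: a switch is equally expected every segment"
             if rho.max() - rho.min() < 0.05 else
             "peaked at tau=5: the moment of change is predictable")
    print(f"  spread max-min = {rho.max() - rho.min():.3f} ({shape})\n")
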