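"""Generate one synthetic subject and recover their parameters.

A subject with a known NMDA rate-constant deficit is drawn from the
cohort generator (finite-epoch cross-spectral estimate), then inverted by
variational Laplace over 2-48 Hz.  Prints fit quality and the posterior
on the deficit parameters.
"""

import numpy as np

from neurodcm import ForwardModel, build_default_network, variational_laplace
from neurodcm.cohort import CohortSpec, generate_cohort
from neurodcm.inversion import InversionConfig

net = build_default_network()
spec = net.param_spec()

cohort = generate_cohort(
    CohortSpec(group_sizes={"nmdar": 1, "encephalopathy": 1, "control": 1},
               seed=42)
)
sid = cohort.table.set_index("group").loc["nmdar", "id"]
truth = cohort.params[sid]

fm = ForwardModel(net, cohort.lead_field, cohort.modes[sid].matrix)
post = variational_laplace(
    cohort.csd[sid].band(2.0, 48.0), fm,
    config=InversionConfig(max_iter=40, tol=0.01, fd_scheme="forward"),
)

print(f"subject {sid}: fit R^2 = {post.r2:.1f}% "
      f"after {len(post.trace)} free-energy evaluations")
print(f"{'parameter':18s} {'truth':>8s} {'posterior':>10s}")
for lab in ("kappa_NMDA.PR", "kappa_NMDA.FL", "kappa_NMDA.FR",
            "g_NMDA_exc.PR", "g_NMDA_exc.FL"):
    est = post.mean[spec.index(lab)]
    print(f"{lab:18s} {truth[lab]:8.2f} {est:10.3f}")
# Log-scale factors below zero mean reduced NMDA function; single-subject
# posteriors recover the direction, and pooling across a cohort (example
# 03) sharpens the attribution.
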