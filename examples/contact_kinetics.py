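"""Recover unbinding kinetics from a synthetic unfolding ensemble.

Emulates the ensemble-averaged decay of the fraction of native
intermolecular contacts (Q_inter) in a set of 50 independent
high-temperature unbinding runs: every native contact is a two-state
Markov chain whose ensemble mean is exactly B + A exp(-t/tau).  The
single-exponential fit of the averaged trace should recover the
generating constants.
"""

from synfold import SyntheticKineticsSpec, fit_exponential, gen_contact_traces

# tau = 1.61 ns, A = 0.23, B = 0.17: the overall intermolecular decay
spec = SyntheticKineticsSpec.from_fit_params(
    tau_ns=1.61, amplitude=0.23, offset=0.17,
    n_runs=50, n_contacts=62, dt_ps=10.0, t_total_ns=10.0, seed=42)

traces = gen_contact_traces(spec)
fit = fit_exponential(traces.times_ns, traces.mean(), fit_start=0.02)

print(f"generating constants: tau = {spec.tau_ns} ns, "
      f"A = {spec.amplitude:.2f}, B = {spec.offset:.2f}")
print(f"fitted constants:     tau = {fit.tau:.2f} ns, "
      f"A = {fit.amplitude:.2f}, B = {fit.offset:.2f}, R = {fit.correlation:.3f}")
print()
print("tau is the relaxation time of unbinding; B is the plateau of")
print("persistent contacts; R is the correlation between fit and data.")
print("A single 50-run ensemble carries ~8-10% statistical spread in tau.")
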