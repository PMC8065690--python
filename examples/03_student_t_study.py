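"""A desk-scale run of the Student-t latent-variable simulation study.

One dataset of T observations from a Student-t with location 0, precision 1
and 8 degrees of freedom; per replication, fresh Gibbs chains for the
unrestricted (mu free) and restricted (mu = 0) scale-mixture models, a
trimming subset D = (A x B) ∩ C built from the two samplers' outputs, and
the four ratio-mean estimators of log10 BF. The latent dimension equals T,
which is what breaks the uncorrected R-vs-U mean. Chain lengths here are cut
far below the 20,000-iteration study scale so the example runs in ~a minute.
"""

from bftrim.student_t import StudentTConfig, run_simulation_study

summary = run_simulation_study(
    [StudentTConfig(T=200, mu_true=0.0)],
    n_replications=5,
    n_iter=4_400,
    burn_in=400,
    seed=7,
    came_k_prior=10_000,
    came_k_posterior=10_000,
)

bench = summary.benchmarks.iloc[0]
print(
    f"CAME benchmark log10 BF_U,R = {bench['came_log10_bf_ur']:+.3f} "
    f"(NSE {bench['nse_log10']:.3f})"
)
print(summary.table.round(3).to_string(index=False))
# Reading the table: M/SD are the mean and spread of each estimator over
# replications; AE and RMSE are errors against the CAME benchmark. The
# corrected estimators (",D" suffix) sit on the benchmark in both directions,
# while the uncorrected R-vs-U mean is far below its target -- the downward
# "pseudo-bias" of untrimmed ratio means in high-dimensional latent spaces.
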