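"""Plan and analyse a measurement-reliability study.

Bonett's approximation sizes the study (36 subjects for a planning ICC of
0.8 with a 0.2-wide 95% CI and three raters); repeated sessions with the
bundled within-/between-observer error magnitudes are then simulated and
summarised as ICC(2,1), RMS-SD and CV per parameter.
"""

import calcmorph as cm

n = cm.bonett_n(rho0=0.8, width=0.2, k=3, alpha=0.05)
print(f"Bonett planning: {n} subjects "
      "(ICC 0.8, CI width 0.2, 3 raters, alpha 0.05)")

cohort = cm.sample_cohort(cm.study_cohort_spec(seed=2)).sample(
    n=n, random_state=0).sort_index()
sessions = cm.simulate_sessions(cohort, cm.study_error_spec(seed=3))
report = cm.reliability_report(sessions)

print("\nintra-observer (examiner 1, 2 sessions):")
print(f"{'param':6s} {'ICC':>6s} {'95% CI':>16s} {'RMS-SD':>7s} {'CV%':>5s}")
for _, r in report["intra"].iterrows():
    cv = f"{r.cv_pct:5.1f}" if r.cv_pct == r.cv_pct else "   NA"
    print(f"{r.parameter:6s} {r.icc:6.3f} "
          f"[{r.ci_low:6.3f}, {r.ci_high:6.3f}] {r.rms_sd:7.2f} {cv}")

print("\ninter-observer (3 examiners jointly, first sessions):")
for _, r in report["inter_overall"].iterrows():
    print(f"  {r.parameter:4s} ICC={r.icc:.3f} "
          f"[{r.ci_low:.3f}, {r.ci_high:.3f}]")

# High ICCs (> 0.9 intra, > 0.8 inter) and sub-unit RMS-SDs mirror a
# reliable measurement protocol; CV is reported for lengths and areas only.
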