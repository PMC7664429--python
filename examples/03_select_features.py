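"""Reduce the 26-feature battery with the CV and WCSS filters.

The coefficient-of-variation filter drops features with under 50% relative
variability; the univariate two-cluster WCSS filter then keeps the 13
features along which the cohort looks most like two groups.
"""

from edaffect import SynthConfig, compute_features, cv_filter, simulate_cohort, wcss_filter

cohort = simulate_cohort(SynthConfig(seed=1))
matrix = compute_features(cohort.sessions)[1]

after_cv, cv_report = cv_filter(matrix, threshold=0.5)
print(f"CV filter: {len(matrix.feature_names)} -> "
      f"{len(after_cv.feature_names)} features")
rejected = [n for n, k in cv_report.kept.items() if not k]
print(f"  rejected (|CV| < 0.5): {', '.join(rejected)}")

after_wcss, wcss_report = wcss_filter(after_cv, top_k=13)
print(f"WCSS filter: kept the 13 smallest-WCSS features:")
for name in after_wcss.feature_names:
    print(f"  {name:22s} wcss={wcss_report.wcss[name]:10.4f}")
# Small WCSS = the feature's values fall into two tight clusters, i.e. it
# separates the cohort; large WCSS = diffuse, class-uninformative spread.
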