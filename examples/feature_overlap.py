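"""Which genomic feature types do called locales fall on?

Uses the synthetic truth annotations (pattern names stand in for feature
types such as gene/transposable_element) to show the tally: for each type,
how many locales overlap at least one such feature, and how many distinct
features are hit.  Nested features all count — a locale inside a gene inside
a transposable element increments both types.
"""

from nibls import (
    CallerConfig,
    FixtureConfig,
    call_locales,
    feature_overlap_counts,
    simulate,
)

data = simulate(FixtureConfig(seed=23, n_locales=30, background_reads=100,
                              locale_pattern="mixed"))
locales = call_locales(list(data.reads), CallerConfig(10, 0.25))
table = feature_overlap_counts(locales, data.truth_loci)
print(f"{len(locales)} locales vs {len(data.truth_loci)} annotated features\n")
print(table.to_string(index=False))
print("\nn_locales = locales overlapping >=1 feature of the type; "
      "n_features = distinct features of the type overlapped by >=1 locale")
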