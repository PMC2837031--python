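"""How robust are the called locales to the choice of (M, C)?

Calls locales at three nearby parameter settings, then measures (a) the
pairwise proportion of locales in one set that overlap any locale of the
other — an asymmetric measure when set sizes differ — and (b) the number of
locales with exactly identical coordinates in each Venn region of the three
sets.
"""

import itertools

from nibls import (
    CallerConfig,
    FixtureConfig,
    call_locales,
    identical_locale_counts,
    overlap_proportion,
    simulate,
)

data = simulate(FixtureConfig(seed=11, n_locales=25, background_reads=250,
                              locale_pattern="mixed"))
reads = list(data.reads)

settings = {"M5_C0.1": (5, 0.1), "M10_C0.4": (10, 0.4), "M20_C0.5": (20, 0.5)}
sets = {name: call_locales(reads, CallerConfig(*mc)) for name, mc in settings.items()}
for name, locs in sets.items():
    print(f"{name}: {len(locs)} locales")

print("\npairwise overlap proportions (rows are the reference set):")
for a, b in itertools.permutations(sets, 2):
    print(f"  {a} vs {b}: {overlap_proportion(sets[a], sets[b]):.1f}%")

print("\nexactly-identical locales per Venn region:")
regions = identical_locale_counts(sets)
for combo in sorted(regions, key=lambda c: (len(c), c)):
    print(f"  {' & '.join(combo)}: {regions[combo]}")
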