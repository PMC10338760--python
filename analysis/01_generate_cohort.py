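#!/usr/bin/env python
"""Generate the study cohort: 30 synthetic head phantoms mixing
high-contrast (ΔHU = −40, clearly visible hypodense cavity) and
zero-contrast (ΔHU = 0, invisible cavity) regimes at σ = 5 HU, plus a few
discontinuous and supratentorial cases to exercise the continuity and
location criteria.

Writes NIfTI volumes/masks, a JSON manifest and a truth table under
scratch/cohort/ (bulky imaging intermediates live under scratch/; only
text tables go to results/).
"""

from pathlib import Path

from cavityqa.phantom import PhantomSpec, generate_cohort

OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"
SHAPE = (96, 96, 48)
SEED = 20260926


def main() -> None:
    base = PhantomSpec(shape=SHAPE, sigma_hu=5.0)
    regimes = [
        (base, 18),  # high-contrast, continuous, in-fossa (delta_hu = -40)
        (PhantomSpec(shape=SHAPE, sigma_hu=5.0, delta_hu=0.0), 8),  # invisible
        (PhantomSpec(shape=SHAPE, sigma_hu=5.0, n_components=2), 2),  # discontinuous
        (PhantomSpec(shape=SHAPE, sigma_hu=5.0, in_fossa=False), 2),  # supratentorial
    ]
    cases, manifest = generate_cohort(regimes, OUT, seed=SEED)
    print(f"wrote {len(cases)} cases")
    print(f"manifest: {manifest}")
    print(f"truth table: {OUT / 'truth.csv'}")


if __name__ == "__main__":
    main()
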