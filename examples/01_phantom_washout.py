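"""Generate one phantom lesion per class and run conventional densitometry.

Prints the unenhanced mean attenuation (HU), the absolute and relative
washout percentages, and the conventional benign/indeterminate call.  The
incidentaloma clears on washout; the lipid-poor adenoma and the carcinoma
both remain indeterminate — the gap radiomic texture analysis targets.
"""

from adrenomics import (
    PhantomSpec,
    WashoutResult,
    classify_washout,
    extract_voi,
    generate_phantom,
    mean_densitometry,
)

for label in ("carcinoma", "adenoma", "incidentaloma"):
    volumes, mask = generate_phantom(PhantomSpec.for_class(label, seed=1))
    means = {phase: mean_densitometry(extract_voi(vol, mask)) for phase, vol in volumes.items()}
    res = WashoutResult.compute(means["unenhanced"], means["venous"], means["delayed"])
    call, _ = classify_washout(res)
    print(
        f"{label:14s} unenhanced {means['unenhanced']:6.1f} HU | "
        f"absolute washout {res.absolute_washout:5.1f}% | "
        f"relative washout {res.relative_washout:5.1f}% | {call}"
    )
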