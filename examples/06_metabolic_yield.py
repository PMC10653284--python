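"""Maximum theoretical carbon yields from a toy fermentation model.

A demand reaction is added for the product and its flux maximized by
linear programming; the carbon yield divides product carbon flux by total
carbon influx.  Lactate fermentation conserves all glucose carbon (yield
1.0); ethanol fermentation loses a third as CO2 (yield 2/3).
"""

from polyscreen import (
    filter_yield_targets,
    generate_toy_metabolic_model,
    max_theoretical_yield,
)

for variant, product in [("lactate", "lac"), ("ethanol_co2", "etoh")]:
    model = generate_toy_metabolic_model(variant)
    res = max_theoretical_yield(model, product)
    print(
        f"{variant:12s} max {product} flux = {res.demand_flux:5.1f} mmol/gDW/h, "
        f"carbon yield = {res.carbon_yield:.4f}"
    )
    kept = filter_yield_targets(model, [res])
    print(f"             passes polymer-relevance filter: {kept}")
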