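"""Food-frequency scoring: categories -> servings/day -> scores -> tertiles.

Frequency categories convert by the midpoint convention (e.g. '1-2
times/week' -> 1.5/7 servings/day); item servings sum into the high-sugar
and unhealthy scores, which are cut at the published tertile boundaries.
"""

from acemod import assign_tertile, compose_food_score, default_ffq_mapping, ffq_to_servings

mapping = default_ffq_mapping()

for cat in ("never", "1-2 times/week", "1 time/day", "3 times/day"):
    print(f"{cat:>16s} -> {ffq_to_servings(cat, mapping):.4f} servings/day")

# a respondent's high-sugar items (all 12 must be present; missing items
# are an error, never silently zero)
responses = {
    "cookies": "1-2 times/week", "crackers": "never", "cake": "1-3 times/month",
    "chocolate": "3-4 times/week", "candy": "1-2 times/week", "ice cream": "never",
    "jam": "1 time/day", "berry cream": "never", "juice": "2 times/day",
    "energy drink": "never", "honey": "1-3 times/month", "ketchup": "1-2 times/week",
}
servings = {item: ffq_to_servings(freq, mapping) for item, freq in responses.items()}
score = compose_food_score(servings, "high_sugar", mapping)
tertile = assign_tertile(score, "high_sugar")
print(f"\nhigh-sugar score: {score:.3f} servings/day -> tertile: {tertile}")
print("(published high-sugar cutpoints: low <= 1.56, high >= 2.90)")
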