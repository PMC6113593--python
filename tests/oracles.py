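"""Independent brute-force oracles, coded separately from the library.

These recompute expected values with plain loops over plain dicts so
that engine results can be checked against an implementation that shares
no code with the path under test.
"""


def brute_force_per_100g(ingredients, composition, include_auxiliary=False):
    """Weighted nutrient sum for 100 g of a dish.

    ``ingredients``: iterable of (name, raw_weight_g, auxiliary) in recipe
    order. ``composition``: {name: {nutrient: amount-per-100g or None}}.
    Returns {nutrient: amount or None}; a nutrient is None when any
    counted ingredient lacks it.
    """
    counted = [
        (name, weight)
        for name, weight, auxiliary in ingredients
        if include_auxiliary or not auxiliary
    ]
    total = sum(weight for _, weight in counted)
    nutrient_names = []
    for comp in composition.values():
        for key in comp:
            if key not in nutrient_names:
                nutrient_names.append(key)

    result = {}
    for nutrient in nutrient_names:
        amount = 0.0
        absent = False
        for name, weight in counted:
            value = composition[name].get(nutrient)
            if value is None:
                absent = True
            else:
                # weight/total of the 100 g serving, times per-100 g value
                amount += (weight / total) * value
        result[nutrient] = None if absent else amount
    return result


def brute_force_tally(labels):
    """Plain counting oracle for distribution reports."""
    counts = {}
    for label in labels:
        counts[label] = counts.get(label, 0) + 1
    return counts


def brute_force_deviation(calculated, measured):
    """|c - m| / m * 100 with None when the baseline m is zero."""
    if measured == 0:
        return None
    diff = calculated - measured
    if diff < 0:
        diff = -diff
    return diff / measured * 100.0
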