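"""Apply the published pooled South African discriminant equations.

The registry carries the six univariate and six multivariate published
functions verbatim. A new case is classified by the sign of its score
relative to the sectioning point 0.
"""

from patellasex import classify, published_equations

registry = published_equations()
print(f"{len(registry)} published functions: {sorted(registry)}\n")

# an unknown patella: measurements in mm
case = {"maxh": 41.0, "maxb": 43.2, "maxt": 19.8, "haf": 29.5,
        "mafb": 19.1, "lafb": 25.6}

for name in ("maxh", "stepwise", "D1"):
    fn = registry[name]
    result = classify(fn, case)
    print(f"{name:9s} score {result.score:+.3f} → {result.sex} "
          f"(|score| is the distance from the sectioning point; larger "
          "means a more confident call)")
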