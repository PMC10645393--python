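"""Set-overlap statistics and hypergeometric category enrichment.

Reproduces the worked overlap arithmetic for two interactor lists of 435
and 467 proteins sharing 422 members, attaches an exact hypergeometric p
against a universe, and runs a small GMT enrichment.
"""

from apexflux import enrich_categories, hypergeom_overlap_test, percent_overlap

minus_ir = {f"P{i:04d}" for i in range(435)}
plus_ir = {f"P{i:04d}" for i in range(13, 480)}

res = percent_overlap(minus_ir, plus_ir)
print(
    f"|A|={res.size_a} |B|={res.size_b} shared={res.size_intersection} "
    f"-> {res.percent_overlap:.1f}% of the union (~{res.percent_rounded}%)"
)

universe = {f"P{i:04d}" for i in range(2000)}
res = hypergeom_overlap_test(minus_ir, plus_ir, universe)
print(f"hypergeometric P(X >= {res.size_intersection}) = {res.hypergeom_p:.3g} "
      f"(universe {res.universe_size})")

gmt = {
    "splicing": {f"P{i:04d}" for i in range(0, 60)},
    "transcription": {f"P{i:04d}" for i in range(400, 700)},
    "unrelated": {f"P{i:04d}" for i in range(1500, 1600)},
}
for row in enrich_categories(minus_ir, gmt, universe):
    print(
        f"  {row.category:14s} overlap={row.k_overlap:3d}/{row.category_size:3d} "
        f"p={row.p_value:.3g} q={row.q_value:.3g}"
    )
# small p/q: the query list contains far more of the category's members
# than a random draw of its size from the universe would.
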