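"""Map genotypes onto the model's single control parameter gamma.

Each adhesion molecule (Fas3 in Tin-like cells, Ten-m in Svp-like cells)
contributes a component gamma; a genotype keeps only the components whose
differential expression pattern survives.  Losing the Svp fate or both
molecules flattens all adhesion differences (gamma = 0).
"""

import cellmatch as cm
from cellmatch import experiments as ex

kw = dict(gamma_fas3=0.25, gamma_tenm=0.25)
print(f"{'genotype':22s} {'pattern':8s} gamma (um)")
for name in ex.GENOTYPES:
    pattern, g, params = ex.genotype_to_params(ex.GenotypeSpec(name, **kw))
    print(f"{name:22s} {pattern:8s} {g:.2f}")

g_wt = ex.genotype_to_params(ex.GenotypeSpec("WT", **kw))[1]
g_f = ex.genotype_to_params(ex.GenotypeSpec("fas3_null", **kw))[1]
g_t = ex.genotype_to_params(ex.GenotypeSpec("tenm_null", **kw))[1]
print(f"\nsum rule: gamma_WT = {g_wt:.2f} = "
      f"gamma(fas3-/-) + gamma(tenm-/-) = {g_f:.2f} + {g_t:.2f}")
# With equal components the two molecules contribute equally to matching;
# the single mutants each retain half the wild-type gamma.
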