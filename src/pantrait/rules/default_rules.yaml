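# Extraction rules for primary-metabolism functions from subsystem
# annotation tables.  Categories are listed in report order; matching of
# category / subsystem / subcategory names is case-insensitive.
retained_categories:
  - amino acids and derivatives
  - carbohydrates
  - cofactors, vitamins, prosthetic groups, pigments
  - fatty acids, lipids, and isoprenoids
  - nitrogen metabolism
  - nucleosides and nucleotides

# Subsystems associated with secondary metabolism; removed wherever they
# occur within the retained categories.
removed_subsystems:
  - cyanate hydrolysis
  - hopanes
  - polyhydroxybutyrate metabolism
  - nitrilase
  - nitrosative stress

# Per-category subcategory removals (applied after category selection).
removed_subcategories:
  nucleosides and nucleotides:
    - detoxification
    - no subcategory

# In every retained category not listed above, records whose subcategory is
# the literal "no subcategory" are relabeled "other".
no_subcategory_relabel: other
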