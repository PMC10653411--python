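# Representative antidiabetic formulary mapped to Multum-style therapeutic
# categories.  Editable: extend `categories` (drug -> category) and, for
# combination products, `combinations` (product -> ingredient list).  Drug
# names are matched case-insensitively after whitespace normalization.
categories:
  # biguanides
  metformin: biguanides
  # sulfonylureas
  glimepiride: SUs
  glipizide: SUs
  glyburide: SUs
  chlorpropamide: SUs
  tolazamide: SUs
  # DPP-4 inhibitors
  sitagliptin: DPP-4is
  saxagliptin: DPP-4is
  linagliptin: DPP-4is
  alogliptin: DPP-4is
  # SGLT2 inhibitors
  empagliflozin: SGLT2is
  canagliflozin: SGLT2is
  dapagliflozin: SGLT2is
  ertugliflozin: SGLT2is
  # GLP-1 receptor agonists
  liraglutide: GLP-1RAs
  exenatide: GLP-1RAs
  dulaglutide: GLP-1RAs
  semaglutide: GLP-1RAs
  lixisenatide: GLP-1RAs
  albiglutide: GLP-1RAs
  # thiazolidinediones
  pioglitazone: TZDs
  rosiglitazone: TZDs
  # meglitinides
  repaglinide: meglitinides
  nateglinide: meglitinides
  # alpha-glucosidase inhibitors
  acarbose: AGIs
  miglitol: AGIs
  # insulins (ingredient-level distinctions retained)
  insulin glargine: insulin
  insulin detemir: insulin
  insulin degludec: insulin
  insulin aspart: insulin
  insulin lispro: insulin
  insulin glulisine: insulin
  insulin isophane: insulin
  insulin regular: insulin
  # combination products
  metformin/sitagliptin: combinations
  metformin/saxagliptin: combinations
  metformin/linagliptin: combinations
  metformin/alogliptin: combinations
  glyburide/metformin: combinations
  glipizide/metformin: combinations
  pioglitazone/metformin: combinations
  rosiglitazone/metformin: combinations
  empagliflozin/linagliptin: combinations
  canagliflozin/metformin: combinations
  dapagliflozin/metformin: combinations
  empagliflozin/metformin: combinations
  ertugliflozin/sitagliptin: combinations
  glimepiride/pioglitazone: combinations
  alogliptin/pioglitazone: combinations
  insulin degludec/liraglutide: combinations
  insulin glargine/lixisenatide: combinations
combinations:
  metformin/sitagliptin: [metformin, sitagliptin]
  metformin/saxagliptin: [metformin, saxagliptin]
  metformin/linagliptin: [metformin, linagliptin]
  metformin/alogliptin: [metformin, alogliptin]
  glyburide/metformin: [glyburide, metformin]
  glipizide/metformin: [glipizide, metformin]
  pioglitazone/metformin: [pioglitazone, metformin]
  rosiglitazone/metformin: [rosiglitazone, metformin]
  empagliflozin/linagliptin: [empagliflozin, linagliptin]
  canagliflozin/metformin: [canagliflozin, metformin]
  dapagliflozin/metformin: [dapagliflozin, metformin]
  empagliflozin/metformin: [empagliflozin, metformin]
  ertugliflozin/sitagliptin: [ertugliflozin, sitagliptin]
  glimepiride/pioglitazone: [glimepiride, pioglitazone]
  alogliptin/pioglitazone: [alogliptin, pioglitazone]
  insulin degludec/liraglutide: [insulin degludec, liraglutide]
  insulin glargine/lixisenatide: [insulin glargine, lixisenatide]
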