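# Default disease/modifier lexicon: canonical <TAB> entity_type <TAB> subtype <TAB> pipe-separated variants.
# Reconstructed starting vocabulary of standard UK neuroradiology terms; fully
# overridable by passing an alternative file of the same shape.
infarct	ischaemic_stroke		infarct|infarction|ischaemic stroke|ischaemic change|ischaemic damage|cerebral infarct|cerebral infarction|ischaemic lesion
haemorrhage	haemorrhagic_stroke		haemorrhage|haematoma|bleed|blood|haemorrhagic stroke|intracranial haemorrhage|intracerebral haemorrhage|intracranial bleed|intracerebral bleed|intracerebral haematoma|parenchymal haemorrhage|parenchymal haematoma
stroke	stroke_unspecified		stroke|cva|cerebrovascular accident|cerebrovascular event
subarachnoid haemorrhage	subarachnoid_haemorrhage		subarachnoid haemorrhage|subarachnoid blood|subarachnoid bleed|sah
subdural haematoma	subdural_haematoma		subdural haematoma|subdural haemorrhage|subdural bleed|subdural blood|subdural collection|subdural hygroma|subdural fluid collection
microbleed	microbleed		microbleed|microhaemorrhage|micro-bleed|cerebral microbleed
haemorrhagic transformation	haemorrhagic_transformation		haemorrhagic transformation|haemorrhagic conversion
atrophy	atrophy		atrophy|involution|volume loss|atrophic change|cerebral atrophy|cerebellar atrophy
small vessel disease	small_vessel_disease		small vessel disease|small-vessel disease|microangiopathy|microangiopathic change|white matter low attenuation|leukoaraiosis|small vessel ischaemia|microvascular change|periventricular low attenuation
tumour	tumour	other	tumour|tumor|mass|lesion|mass lesion|neoplasm|space-occupying lesion|space occupying lesion|enhancing mass
meningioma	tumour	meningioma	meningioma|falcine meningioma|convexity meningioma
glioma	tumour	glioma	glioma|glioblastoma|astrocytoma|gbm|high-grade glioma|low-grade glioma
metastasis	tumour	metastasis	metastasis|metastases|secondary deposit|metastatic deposit|metastatic lesion|metastatic disease|secondary tumour
recent	time_recent		recent|acute|new|fresh|early
old	time_old		old|chronic|mature|established|long-standing|longstanding|original|previous|remote
deep	loc_deep		deep|lacunar|lacune|basal ganglia|thalamus|thalamic|internal capsule|pons|pontine|brainstem|capsular|centrum semiovale|corona radiata|caudate|lentiform nucleus
cortical	loc_cortical		cortical|cortex|cerebral cortex|lobar|frontal|parietal|temporal|occipital|frontoparietal|temporoparietal|parieto-occipital|fronto-parietal|insular
aneurysmal	mod_aneurysmal		aneurysmal|aneurysm
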