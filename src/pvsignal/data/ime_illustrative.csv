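pt
Macular oedema
Optic neuritis
Blindness
Leukopenia
Lymphopenia
Hemiparesis
Progressive multifocal leukoencephalopathy
Bradycardia
Atrioventricular block first degree
Seizure
Pneumonia
Basal cell carcinoma
Breast cancer
Thrombosis
Myocardial infarction
Pulmonary embolism
Sepsis
Atrial fibrillation
Nephrolithiasis
Syncope
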