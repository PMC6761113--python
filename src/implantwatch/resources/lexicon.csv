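surface,entity_type,canonical_id,manufacturer,model,component,subclass
trilogy,implant,zimmer_biomet:trilogy,Zimmer Biomet,Trilogy,acetabular,
zimmer trilogy,implant,zimmer_biomet:trilogy,Zimmer Biomet,Trilogy,acetabular,
zimmer biomet trilogy,implant,zimmer_biomet:trilogy,Zimmer Biomet,Trilogy,acetabular,
trilogy cup,implant,zimmer_biomet:trilogy,Zimmer Biomet,Trilogy,acetabular,
continuum,implant,zimmer_biomet:continuum,Zimmer Biomet,Continuum,acetabular,
zimmer continuum,implant,zimmer_biomet:continuum,Zimmer Biomet,Continuum,acetabular,
zimmer biomet continuum,implant,zimmer_biomet:continuum,Zimmer Biomet,Continuum,acetabular,
ringloc,implant,zimmer_biomet:ringloc,Zimmer Biomet,RingLoc,acetabular,
zimmer ringloc,implant,zimmer_biomet:ringloc,Zimmer Biomet,RingLoc,acetabular,
zimmer biomet ringloc,implant,zimmer_biomet:ringloc,Zimmer Biomet,RingLoc,acetabular,
ranawat/burstein,implant,zimmer_biomet:ranawat_burstein,Zimmer Biomet,Ranawat/Burstein,acetabular,
zimmer ranawat/burstein,implant,zimmer_biomet:ranawat_burstein,Zimmer Biomet,Ranawat/Burstein,acetabular,
zimmer biomet ranawat/burstein,implant,zimmer_biomet:ranawat_burstein,Zimmer Biomet,Ranawat/Burstein,acetabular,
versys,implant,zimmer_biomet:versys,Zimmer Biomet,VerSys,femoral,
versys stem,implant,zimmer_biomet:versys,Zimmer Biomet,VerSys,femoral,
zimmer versys,implant,zimmer_biomet:versys,Zimmer Biomet,VerSys,femoral,
zimmer biomet versys,implant,zimmer_biomet:versys,Zimmer Biomet,VerSys,femoral,
m/l taper,implant,zimmer_biomet:ml_taper,Zimmer Biomet,M/L Taper,femoral,
zimmer m/l taper,implant,zimmer_biomet:ml_taper,Zimmer Biomet,M/L Taper,femoral,
zimmer biomet m/l taper,implant,zimmer_biomet:ml_taper,Zimmer Biomet,M/L Taper,femoral,
taperloc,implant,zimmer_biomet:taperloc,Zimmer Biomet,Taperloc,femoral,
biomet taperloc,implant,zimmer_biomet:taperloc,Zimmer Biomet,Taperloc,femoral,
zimmer biomet taperloc,implant,zimmer_biomet:taperloc,Zimmer Biomet,Taperloc,femoral,
longevity,implant,zimmer_biomet:longevity,Zimmer Biomet,Longevity,liner,
longevity liner,implant,zimmer_biomet:longevity,Zimmer Biomet,Longevity,liner,
zimmer longevity,implant,zimmer_biomet:longevity,Zimmer Biomet,Longevity,liner,
pinnacle,implant,depuy:pinnacle,Depuy,Pinnacle,acetabular,
depuy pinnacle,implant,depuy:pinnacle,Depuy,Pinnacle,acetabular,
pinnacle cup,implant,depuy:pinnacle,Depuy,Pinnacle,acetabular,
duraloc,implant,depuy:duraloc,Depuy,Duraloc,acetabular,
depuy duraloc,implant,depuy:duraloc,Depuy,Duraloc,acetabular,
aml,implant,depuy:aml,Depuy,AML,femoral,
depuy aml,implant,depuy:aml,Depuy,AML,femoral,
aml stem,implant,depuy:aml,Depuy,AML,femoral,
corail,implant,depuy:corail,Depuy,Corail,femoral,
depuy corail,implant,depuy:corail,Depuy,Corail,femoral,
summit,implant,depuy:summit,Depuy,Summit,femoral,
depuy summit,implant,depuy:summit,Depuy,Summit,femoral,
endurance,implant,depuy:endurance,Depuy,Endurance,femoral,
depuy endurance,implant,depuy:endurance,Depuy,Endurance,femoral,
acetabular cup,implant,generic:acetabular_cup,,,acetabular,
femoral stem,implant,generic:femoral_stem,,,femoral,
prosthesis,implant,generic:prosthesis,,,unknown,
revision,complication,comp:revision,,,,revision
revision surgery,complication,comp:revision,,,,revision
revision arthroplasty,complication,comp:revision,,,,revision
revision of the hip replacement,complication,comp:revision,,,,revision
component exchange,complication,comp:revision,,,,revision
liner wear,complication,comp:component_wear,,,,component_wear
polyethylene wear,complication,comp:component_wear,,,,component_wear
component wear,complication,comp:component_wear,,,,component_wear
extreme liner wear,complication,comp:component_wear,,,,component_wear
eccentric wear,complication,comp:component_wear,,,,component_wear
dislocation,complication,comp:mechanical_failure,,,,mechanical_failure
loosening,complication,comp:mechanical_failure,,,,mechanical_failure
aseptic loosening,complication,comp:mechanical_failure,,,,mechanical_failure
periprosthetic fracture,complication,comp:mechanical_failure,,,,mechanical_failure
implant failure,complication,comp:mechanical_failure,,,,mechanical_failure
component migration,complication,comp:mechanical_failure,,,,mechanical_failure
osteolysis,complication,comp:particle_disease,,,,particle_disease
particle disease,complication,comp:particle_disease,,,,particle_disease
metallosis,complication,comp:particle_disease,,,,particle_disease
pseudotumor,complication,comp:particle_disease,,,,particle_disease
radiolucency,complication,comp:radiographic_abnormality,,,,radiographic_abnormality
radiolucent line,complication,comp:radiographic_abnormality,,,,radiographic_abnormality
lucency,complication,comp:radiographic_abnormality,,,,radiographic_abnormality
subsidence,complication,comp:radiographic_abnormality,,,,radiographic_abnormality
periprosthetic infection,complication,comp:infection,,,,infection
prosthetic joint infection,complication,comp:infection,,,,infection
infected prosthesis,complication,comp:infection,,,,infection
deep infection,complication,comp:infection,,,,infection
septic joint,complication,comp:infection,,,,infection
hip,anatomy,anat:hip,,,,
left hip,anatomy,anat:hip,,,,
right hip,anatomy,anat:hip,,,,
groin,anatomy,anat:groin,,,,
thigh,anatomy,anat:thigh,,,,
knee,anatomy,anat:knee,,,,
left knee,anatomy,anat:knee,,,,
right knee,anatomy,anat:knee,,,,
buttock,anatomy,anat:buttock,,,,
greater trochanter,anatomy,anat:trochanter,,,,
lower back,anatomy,anat:lower_back,,,,
shoulder,anatomy,anat:shoulder,,,,
pain,pain,pain:pain,,,,
hip pain,pain,pain:pain,,,,
tenderness,pain,pain:tenderness,,,,
aching,pain,pain:aching,,,,
discomfort,pain,pain:discomfort,,,,
soreness,pain,pain:soreness,,,,
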