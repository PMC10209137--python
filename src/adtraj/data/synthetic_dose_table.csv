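drug_name,category,min_dose,max_dose
citalopram,SSRI,20,40
sertraline,SSRI,50,200
paroxetine,SSRI,20,50
fluoxetine,SSRI,20,60
venlafaxine,nSSRI,75,375
duloxetine,nSSRI,60,120
amitriptyline,TriCA,75,300
nortriptyline,TriCA,50,150
clomipramine,TriCA,75,250
mirtazapine,TetraCA,15,45
mianserine,TetraCA,30,90
tranylcypromine,MAOI,20,60
phenelzine,MAOI,45,90
bupropion,other,150,300
agomelatine,other,25,50
diazepam,benzodiazepine,5,40
oxazepam,benzodiazepine,10,120
lorazepam,benzodiazepine,1,7.5
lithiumcarbonate,lithium,600,1800
haloperidol,antipsychotics,1,10
olanzapine,antipsychotics,5,20
quetiapine,antipsychotics,50,800
disulfiram,disulfiram,250,500
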