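gene	sibling_disorders
ADAM10	Bipolar Spectrum Disorders;Down Syndrome;Sleep Disorders
ADCY9	Bipolar Spectrum Disorders;Depressive Disorder;Epilepsy;Schizophrenia;Sleep Disorders
ADCYAP1R1	Anxiety Disorder;Bipolar Spectrum Disorders;Obsessive Compulsive Disorder;Panic Disorder
AKT1	Bipolar Spectrum Disorders;Depressive Disorder;Epilepsy;Fragile X Syndrome;Schizophrenia;Tuberous Sclerosis
ATN1	Epilepsy;Fragile X Syndrome;Intellectual Disability;Schizophrenia;Sleep Disorders
DGCR8	Depressive Disorder;Fragile X Syndrome;Schizophrenia;Sleep Disorders
DLGAP4	Anxiety Disorder;Bipolar Spectrum Disorders;Obsessive Compulsive Disorder;Panic Disorder;Schizophrenia;Sleep Disorders
HSPA1L	Bipolar Spectrum Disorders;Depressive Disorder;Schizophrenia
KCNH2	Epilepsy;Intellectual Disability;Schizophrenia;Sleep Disorders
MEGF10	Bipolar Spectrum Disorders;Schizophrenia;Sleep Disorders
MMP2	Epilepsy;Sleep Disorders;Tuberous Sclerosis
NDE1	Bipolar Spectrum Disorders;Epilepsy;Intellectual Disability;Schizophrenia
NPPB	Anxiety Disorder;Bipolar Spectrum Disorders;Obsessive Compulsive Disorder;Panic Disorder;Sleep Disorders
NRP1	Anxiety Disorder;Bipolar Spectrum Disorders;Obsessive Compulsive Disorder;Panic Disorder;Sleep Disorders
PPP3CB	Attention Deficit Hyperactivity Disorder;Schizophrenia;Sleep Disorders
PRKG1	Attention Deficit Hyperactivity Disorder;Fragile X Syndrome;Schizophrenia;Sleep Disorders
SLC29A2	Depressive Disorder;Epilepsy;Sleep Disorders
SMARCA2	Epilepsy;Intellectual Disability;Schizophrenia;Sleep Disorders
VIPR2	Anxiety Disorder;Bipolar Spectrum Disorders;Depressive Disorder;Down Syndrome;Epilepsy;Intellectual Disability;Obsessive Compulsive Disorder;Panic Disorder;Schizophrenia
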